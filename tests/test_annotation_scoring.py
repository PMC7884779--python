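"""CFD scoring, PAM-disruption annotation, silent mutations, ranking."""

import random
from itertools import product

import pytest

from pegcraft import (
    DesignParams,
    annotate_pam_disruption,
    cfd_score,
    enumerate_pegrnas,
    parse_edit_input,
    propose_silent_pam_disruptors,
    recommend,
)
from pegcraft.annotation_scoring import CODON_TABLE, preferred_codons, translate
from pegcraft.ngrna_design import PE3, PE3B_SEED, NgRNADesign
from pegcraft.pegrna_design import ProtospacerSite, find_protospacers
from pegcraft.sequence_model import StrandedInterval

import oracles


class TestCFD:
    def test_perfect_match_scores_one(self, cfd_matrix):
        spacer = "ACGTACGTACGTACGTACGT"
        assert cfd_score(spacer, spacer, "GG", cfd_matrix) == 1.0

    def test_zero_pam_penalty_zeroes_score(self, cfd_matrix):
        spacer = "ACGTACGTACGTACGTACGT"
        assert cfd_matrix.pam_penalty["AA"] == 0.0
        assert cfd_score(spacer, spacer, "AA", cfd_matrix) == 0.0

    @pytest.mark.parametrize("position", [1, 5, 10, 15, 20])
    @pytest.mark.parametrize("pair", [("A", "G"), ("G", "T"), ("C", "A")])
    def test_single_mismatch_equals_lookup(self, cfd_matrix, position, pair):
        s_base, t_base = pair
        spacer = list("A" * 20)
        target = list("A" * 20)
        spacer[position - 1] = s_base
        target[position - 1] = t_base
        # avoid accidental matches elsewhere: base sequences identical
        expected = cfd_matrix.mismatch_penalty[(s_base, t_base, position)]
        got = cfd_score("".join(spacer), "".join(target), "GG", cfd_matrix)
        assert got == pytest.approx(expected)

    def test_score_non_increasing_with_added_mismatches(self, cfd_matrix):
        rng = random.Random(11)
        for _ in range(25):
            spacer = "".join(rng.choice("ACGT") for _ in range(20))
            target = list(spacer)
            prev = cfd_score(spacer, "".join(target), "GG", cfd_matrix)
            positions = rng.sample(range(20), 6)
            for p in positions:
                target[p] = rng.choice([b for b in "ACGT" if b != spacer[p]])
                score = cfd_score(spacer, "".join(target), "GG", cfd_matrix)
                assert score <= prev + 1e-12
                prev = score

    def test_length_errors(self, cfd_matrix):
        with pytest.raises(ValueError):
            cfd_score("ACGT", "ACGT", "GG", cfd_matrix)
        with pytest.raises(ValueError):
            cfd_score("A" * 20, "A" * 20, "GGG", cfd_matrix)

    def test_all_factors_within_unit_interval(self, cfd_matrix):
        assert all(0 <= v <= 1 for v in cfd_matrix.mismatch_penalty.values())
        assert cfd_matrix.pam_penalty["GG"] == 1.0


def _site_at_zero(seq):
    return next(
        s
        for s in find_protospacers(seq, strand="+")
        if s.protospacer_interval.start == 0
    )


class TestPamDisruption:
    SEQ = "AAAACCCCGGGGTTTTAACC" + "TGG" + "ACGTACGTACGTAC"
    # + strand site at 0: PAM at [20, 23), GG at reference [21, 23)

    def _spec(self, token_at, token):
        s = self.SEQ
        return parse_edit_input(s[:token_at] + token + s[token_at + len(token.split("/")[0]) - 1 :])

    def test_edit_at_pam_n_is_not_disruption(self):
        spec = parse_edit_input(self.SEQ[:20] + "(T/A)" + self.SEQ[21:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is False

    def test_edit_at_first_g_is_disruption(self):
        spec = parse_edit_input(self.SEQ[:21] + "(G/A)" + self.SEQ[22:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is True

    def test_deletion_spanning_pam_is_disruption(self):
        spec = parse_edit_input(self.SEQ[:19] + "(-CTGGA)" + self.SEQ[24:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is True

    def test_substitution_keeping_base_is_not_disruption(self):
        # two-base token where only the non-GG base actually changes
        spec = parse_edit_input(self.SEQ[:20] + "(TG/AG)" + self.SEQ[22:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is False

    def test_insertion_between_the_gs_is_disruption(self):
        spec = parse_edit_input(self.SEQ[:22] + "(+A)" + self.SEQ[22:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is True

    def test_insertion_before_pam_is_not_disruption(self):
        spec = parse_edit_input(self.SEQ[:20] + "(+A)" + self.SEQ[20:])
        site = _site_at_zero(spec.reference_sequence)
        assert annotate_pam_disruption(spec, site) is False

    def test_minus_strand_gg_interval(self):
        # - strand site: CCN at [0, 3); GG of the - strand PAM is ref [0, 2)
        seq = "CCA" + "T" * 25
        site = find_protospacers(seq, strand="-")[0]
        spec = parse_edit_input("(C/A)" + seq[1:])
        assert annotate_pam_disruption(spec, site) is True
        spec2 = parse_edit_input(seq[:2] + "(A/G)" + seq[3:])
        assert annotate_pam_disruption(spec2, site) is False


class TestSilentPamDisruptors:
    def test_all_codon_contexts_stay_synonymous(self):
        """Exhaustive over all 64 codons x 3 codon phases around the PAM GG:
        every proposal leaves the protein unchanged and alters >= 1 GG base."""
        checked = n_with_proposals = 0
        for codon in map("".join, product("ACGT", repeat=3)):
            # context: spacer (20) + N + codon, PAM GG at reference [21, 23);
            # the installed edit sits at 25, safely 3' of the nick at 17
            seq = "ATAT" * 5 + "T" + codon + "ATATAT" + "ATAT" * 4
            if seq[21:23] != "GG":
                continue  # only codons that actually supply the PAM GG
            spec = parse_edit_input(seq[:25] + f"({seq[25]}/C)" + seq[26:])
            sites = [
                s
                for s in find_protospacers(spec.reference_sequence, strand="+")
                if s.protospacer_interval.start == 0
            ]
            assert sites
            for fo in (0, 1, 2):
                proposals = propose_silent_pam_disruptors(
                    spec, sites[0], frame_offset=fo, strand_of_cds="+"
                )
                n_with_proposals += bool(proposals)
                cds_start = (3 - fo) % 3
                for aug in proposals:
                    silent = [e for e in aug.edits if e.ref_start != 25]
                    assert len(silent) == 1
                    (e,) = silent
                    changed = {
                        e.ref_start + i
                        for i, (r, a) in enumerate(zip(e.ref_allele, e.alt_allele))
                        if r != a
                    }
                    assert changed & {21, 22}, "must touch the PAM GG"
                    # silent edit alone must leave the in-frame protein intact
                    ref2 = oracles.splice(
                        seq, [(e.ref_start, e.ref_allele, e.alt_allele)]
                    )
                    span = (len(seq) - cds_start) // 3 * 3
                    assert translate(
                        ref2[cds_start : cds_start + span]
                    ) == translate(seq[cds_start : cds_start + span])
                checked += 1
        assert checked == 12  # 4 GG-prefixed codons x 3 phases
        assert n_with_proposals >= 1

    def test_gly_codon_phase_offers_no_disruptor(self):
        """With the GG on a glycine codon's first two bases every synonym
        varies only the wobble position, so no silent disruptor exists."""
        seq = "ATAT" * 5 + "T" + "GGA" + "ATATAT" + "ATAT" * 4
        spec = parse_edit_input(seq[:25] + f"({seq[25]}/C)" + seq[26:])
        site = _site_at_zero(spec.reference_sequence)
        assert propose_silent_pam_disruptors(spec, site, 0, "+") == []

    def test_trp_codon_has_no_synonyms(self):
        # TGG codon exactly on N+GG: codon TGG at [20, 23)
        seq = "ATAT" * 5 + "TGG" + "ATATAT" + "ATAT" * 4
        spec = parse_edit_input(seq[:5] + f"({seq[5]}/C)" + seq[6:])
        site = _site_at_zero(spec.reference_sequence)
        proposals = propose_silent_pam_disruptors(
            spec, site, frame_offset=1, strand_of_cds="+"
        )
        # frame_offset 1 => codon starts at 20: the codon is TGG (Trp)
        assert proposals == []

    def test_outside_cds_raises(self):
        seq = "ATAT" * 5 + "TGG" + "ATATAT" + "ATAT" * 4
        spec = parse_edit_input(seq[:5] + f"({seq[5]}/C)" + seq[6:])
        site = _site_at_zero(spec.reference_sequence)
        with pytest.raises(ValueError, match="frame required"):
            propose_silent_pam_disruptors(
                spec, site, 0, "+", cds_interval=StrandedInterval(0, 10)
            )


def _mk_ng(category, distance):
    site = ProtospacerSite(
        strand="-",
        spacer="A" * 20,
        pam="AGG",
        protospacer_interval=StrandedInterval(40, 60, "-"),
        nick_position=42,
    )
    mismatches = {PE3: (), PE3B_SEED: (5,), "PE3b_non_seed": (15,)}[category]
    return NgRNADesign(
        site=site,
        nick_distance=distance,
        signed_nick_distance=distance,
        category=category,
        mismatch_positions=mismatches,
    )


class TestRecommend:
    LOCUS = "ATAT" * 5 + "TGG" + "AT" + "CCA" + "TATA" * 30

    def _designs(self):
        text = self.LOCUS[:30] + f"({self.LOCUS[30]}/C)" + self.LOCUS[31:]
        spec = parse_edit_input(text)
        pegs = enumerate_pegrnas(spec)
        assert pegs
        return spec, pegs

    def test_pam_disrupting_peg_wins(self):
        spec, pegs = self._designs()
        from dataclasses import replace

        a = replace(pegs[0], pam_disrupted=False)
        b = replace(pegs[0], pam_disrupted=True, nick_to_edit_distance=9)
        rec = recommend(spec, [a, b], {})
        assert rec.pegrna == b
        assert "prefer_pam_disrupting_pegrna" in rec.rationale

    def test_smaller_nick_to_edit_distance_wins(self):
        spec, pegs = self._designs()
        from dataclasses import replace

        far = replace(pegs[0], nick_to_edit_distance=20)
        near = replace(pegs[0], nick_to_edit_distance=3)
        rec = recommend(spec, [far, near], {})
        assert rec.pegrna == near

    def test_pe3b_seed_ngrna_preferred(self):
        spec, pegs = self._designs()
        peg = pegs[0]
        ngs = [_mk_ng(PE3, 50), _mk_ng("PE3b_non_seed", 50), _mk_ng(PE3B_SEED, 80)]
        rec = recommend(spec, [peg], {peg: ngs})
        assert rec.ngrna is not None and rec.ngrna.category == PE3B_SEED

    def test_pe3_distance_near_fifty(self):
        spec, pegs = self._designs()
        peg = pegs[0]
        ngs = [_mk_ng(PE3, 95), _mk_ng(PE3, 48), _mk_ng(PE3, 5)]
        rec = recommend(spec, [peg], {peg: ngs})
        assert rec.ngrna.nick_distance == 48

    def test_untargetable_result(self):
        spec, _ = self._designs()
        rec = recommend(spec, [], {})
        assert rec.pegrna is None and rec.rationale == ["untargetable"]

    def test_recommend_is_pure(self):
        spec, pegs = self._designs()
        peg = pegs[0]
        ngs = {peg: [_mk_ng(PE3, 48)]}
        r1 = recommend(spec, pegs, ngs)
        r2 = recommend(spec, list(pegs), dict(ngs))
        assert r1.pegrna == r2.pegrna and r1.rationale == r2.rationale


def test_preferred_codons_cover_all_residues():
    table = preferred_codons()
    assert set("ACDEFGHIKLMNPQRSTVWY*") <= set(table)
    for aa, codon in table.items():
        assert CODON_TABLE[codon] == aa
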