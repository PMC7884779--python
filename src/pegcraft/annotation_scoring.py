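"""Design annotation and ranking: CFD specificity, PAM disruption,
silent PAM-disrupting mutations, and the final recommendation.

The CFD (cutting frequency determination) score multiplies per-position
mismatch penalties between a spacer and a target protospacer, times a PAM
penalty for the PAM's 3' dinucleotide.  Here it is computed for the pegRNA
spacer against the EDITED allele at the same locus, as a proxy for
re-engagement of the locus after editing; genome-wide off-target search is
out of scope.

CFD positions are numbered 1-20 from the spacer 5' end (position 20 is
PAM-adjacent) — note this is the opposite orientation from the PAM-proximal
seed numbering used for PE3b classification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

from .ngrna_design import PE3, PE3B_NON_SEED, PE3B_SEED, NgRNADesign
from .pegrna_design import (
    DesignParams,
    PegRNADesign,
    ProtospacerSite,
    _Frame,
)
from .sequence_model import Edit, EditSpec, StrandedInterval, reverse_complement

__all__ = [
    "CFDMatrix",
    "Recommendation",
    "load_cfd_matrix",
    "cfd_score",
    "cfd_vs_edited_allele",
    "annotate_pam_disruption",
    "propose_silent_pam_disruptors",
    "recommend",
    "CODON_TABLE",
    "translate",
    "preferred_codons",
]

_ACGT = "ACGT"

# Standard genetic code, DNA codons.
CODON_TABLE = {
    "".join(c): aa
    for c, aa in zip(
        product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)


def translate(seq: str) -> str:
    """Translate an in-frame DNA sequence with the standard code."""
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


# ---------------------------------------------------------------------------
# CFD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CFDMatrix:
    """Mismatch and PAM penalty lookup tables.

    ``mismatch_penalty`` maps (spacer_base, target_base, position 1-20) to a
    factor in [0, 1]; matched bases implicitly score 1.0.  ``pam_penalty``
    maps the PAM's 3' dinucleotide to a factor in [0, 1] (GG -> 1.0).
    """

    mismatch_penalty: dict = field(default_factory=dict)
    pam_penalty: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.mismatch_penalty.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"penalty {v} for {key} outside [0, 1]")
        for tail, v in self.pam_penalty.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PAM penalty {v} for {tail} outside [0, 1]")


def _read_packaged_tsv(name: str):
    ref = resources.files("pegcraft.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )]
    return rows


def load_cfd_matrix(
    mismatch_path=None, pam_path=None
) -> CFDMatrix:
    """Load the packaged CFD penalty tables (or user-supplied TSV paths).

    The packaged tables are synthetic stand-ins with the published CFD
    schema: one penalty per (spacer base, target base, position) mismatch
    and one per PAM 3' dinucleotide.
    """
    if mismatch_path is None:
        mm_rows = _read_packaged_tsv("cfd_mismatch_penalties_synthetic.tsv")
    else:
        with open(mismatch_path, encoding="utf-8") as fh:
            mm_rows = list(csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            ))
    if pam_path is None:
        pam_rows = _read_packaged_tsv("cfd_pam_penalties_synthetic.tsv")
    else:
        with open(pam_path, encoding="utf-8") as fh:
            pam_rows = list(csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            ))
    mismatch = {
        (r["spacer_base"], r["target_base"], int(r["position"])): float(r["penalty"])
        for r in mm_rows
    }
    pam = {r["pam_tail"]: float(r["penalty"]) for r in pam_rows}
    return CFDMatrix(mismatch_penalty=mismatch, pam_penalty=pam)


def cfd_score(spacer: str, target: str, pam_tail: str, matrix: CFDMatrix) -> float:
    """Multiplicative CFD score for a spacer-target pair in [0, 1]."""
    spacer, target, pam_tail = spacer.upper(), target.upper(), pam_tail.upper()
    if len(spacer) != 20 or len(target) != 20:
        raise ValueError("spacer and target must be 20 nt")
    if len(pam_tail) != 2:
        raise ValueError("pam_tail must be 2 nt")
    for name, s in (("spacer", spacer), ("target", target), ("pam_tail", pam_tail)):
        if set(s) - set(_ACGT):
            raise ValueError(f"{name} contains non-ACGT characters")
    score = matrix.pam_penalty.get(pam_tail, 0.0)
    for i, (s, t) in enumerate(zip(spacer, target), start=1):
        if s != t:
            score *= matrix.mismatch_penalty[(s, t, i)]
    return score


def cfd_vs_edited_allele(
    spec: EditSpec, peg: PegRNADesign, matrix: CFDMatrix
) -> float | None:
    """CFD of the pegRNA spacer against the edited allele at its own locus.

    Scores re-engagement of the locus after successful editing.  Returns
    None when the post-edit window runs off the sequence or contains
    non-ACGT bases.
    """
    frame = _Frame.for_strand(spec, peg.site.strand)
    start = frame.frame_spacer_start(peg.site)
    edited = frame.spec.edited_sequence
    if start + 23 > len(edited):
        return None
    target = edited[start : start + 20]
    pam_tail = edited[start + 21 : start + 23]
    if set(target + pam_tail) - set(_ACGT):
        return None
    return cfd_score(peg.site.spacer, target, pam_tail, matrix)


# ---------------------------------------------------------------------------
# PAM disruption
# ---------------------------------------------------------------------------

def _changed_reference_positions(edit: Edit) -> set[int]:
    """Reference positions whose base is altered (or removed) by the edit."""
    if edit.edit_type == "insertion":
        return set()
    if edit.edit_type == "substitution":
        return {
            edit.ref_start + i
            for i, (r, a) in enumerate(zip(edit.ref_allele, edit.alt_allele))
            if r != a
        }
    # deletion / complex: the whole footprint counts as changed
    return set(range(edit.ref_start, edit.ref_end))


def annotate_pam_disruption(
    spec: EditSpec, peg: PegRNADesign | ProtospacerSite
) -> bool:
    """True when an edit mutates the GG dinucleotide of the site's PAM.

    Substitutions at the PAM's N position do not count.  An insertion counts
    only when its junction splits the two Gs apart.
    """
    site = peg.site if isinstance(peg, PegRNADesign) else peg
    gg = site.pam_gg_reference_interval()
    gg_positions = {gg.start, gg.start + 1}
    for edit in spec.edits:
        if edit.edit_type == "insertion":
            if edit.ref_start == gg.start + 1:  # between the two Gs
                return True
            continue
        if _changed_reference_positions(edit) & gg_positions:
            return True
    return False


# ---------------------------------------------------------------------------
# silent PAM disruptors
# ---------------------------------------------------------------------------

def _spec_with_edits(reference: str, edits: list[Edit]) -> EditSpec:
    """Rebuild an EditSpec from a reference sequence and sorted edits."""
    edits = sorted(edits, key=lambda e: e.ref_start)
    parts, prev = [], 0
    for e in edits:
        if e.ref_start < prev:
            raise ValueError("overlapping edits")
        parts.append(reference[prev : e.ref_start])
        parts.append(e.alt_allele)
        prev = e.ref_end
    parts.append(reference[prev:])
    spec = EditSpec(
        raw_input="",
        reference_sequence=reference,
        edited_sequence="".join(parts),
        edits=edits,
    )
    spec.raw_input = spec.serialize()
    return spec


def propose_silent_pam_disruptors(
    spec: EditSpec,
    peg: PegRNADesign | ProtospacerSite,
    frame_offset: int,
    strand_of_cds: str = "+",
    cds_interval: StrandedInterval | None = None,
    params: DesignParams | None = None,
) -> list[EditSpec]:
    """Synonymous codon changes that mutate the PAM's GG dinucleotide.

    ``frame_offset`` is the codon phase (0/1/2) of position 0 of the
    provided context, read along the CDS strand (for a '-' strand CDS, of
    position 0 of the reverse-complemented context).  Each proposal is the
    original edit set plus one silent substitution, returned as a new
    :class:`EditSpec`; proposals that would collide with existing edits or
    push the combined edit span beyond RTT reach are dropped.  Raises
    ``ValueError("frame required")`` when the PAM GG lies outside the
    annotated CDS.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    params = params or DesignParams()
    site = peg.site if isinstance(peg, PegRNADesign) else peg
    gg = site.pam_gg_reference_interval()
    if cds_interval is not None and not (
        cds_interval.start <= gg.start and gg.end <= cds_interval.end
    ):
        raise ValueError("frame required: PAM GG lies outside the annotated CDS")

    ref = spec.reference_sequence
    n = len(ref)
    if strand_of_cds == "+":
        frame_seq = ref
        to_frame = lambda p: p
        from_frame = lambda p: p
    else:
        frame_seq = reverse_complement(ref)
        to_frame = lambda p: n - 1 - p
        from_frame = lambda p: n - 1 - p

    occupied = set()
    for e in spec.edits:
        occupied |= set(range(e.ref_start, max(e.ref_end, e.ref_start + 1)))

    gg_frame = {to_frame(gg.start), to_frame(gg.start + 1)}
    codon_starts = sorted({p - ((p + frame_offset) % 3) for p in gg_frame})
    proposals: list[EditSpec] = []
    for c in codon_starts:
        if c < 0 or c + 3 > n:
            raise ValueError("frame required: PAM codon extends beyond context")
        codon = frame_seq[c : c + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None or aa == "*":
            continue  # stop codons get no synonymous alternative
        for alt in _SYNONYMS[aa]:
            if alt == codon:
                continue
            changed = [i for i in range(3) if alt[i] != codon[i]]
            if not any(c + i in gg_frame for i in changed):
                continue  # synonymous but does not touch the GG
            lo, hi = min(changed), max(changed)
            ref_positions = sorted(from_frame(c + i) for i in range(lo, hi + 1))
            r0, r1 = ref_positions[0], ref_positions[-1] + 1
            if set(range(r0, r1)) & occupied:
                continue
            ref_allele = ref[r0:r1]
            alt_sub = alt[lo : hi + 1]
            alt_allele = (
                alt_sub if strand_of_cds == "+" else reverse_complement(alt_sub)
            )
            silent = Edit(ref_start=r0, ref_allele=ref_allele, alt_allele=alt_allele)
            augmented = _spec_with_edits(ref, list(spec.edits) + [silent])
            # combined edits must still fit the RTT window of this site
            from .pegrna_design import eligible_peg_spacers

            still = [
                s
                for s in eligible_peg_spacers(augmented, params)
                if s.protospacer_interval == site.protospacer_interval
                and s.strand == site.strand
            ]
            if still:
                proposals.append(augmented)
    return proposals


# ---------------------------------------------------------------------------
# recommendation
# ---------------------------------------------------------------------------

@dataclass
class Recommendation:
    """Best pegRNA (+ optional ngRNA) with the ordered rule trace."""

    pegrna: PegRNADesign | None
    ngrna: NgRNADesign | None
    rationale: list[str]

    @property
    def targetable(self) -> bool:
        return self.pegrna is not None


_CATEGORY_RANK = {PE3B_SEED: 0, PE3B_NON_SEED: 1, PE3: 2}


def _peg_tiebreak(p: PegRNADesign) -> tuple:
    return (
        p.nick_to_edit_distance,
        p.site.protospacer_interval.start,
        0 if p.site.strand == "+" else 1,
    )


def rank_pegrnas(pegs: list[PegRNADesign], rationale=None) -> list[PegRNADesign]:
    """Order designs by the recommendation rules (best first).

    Rules, in order: PAM-disrupting first; smaller nick-to-edit distance;
    PBS length closest to 13 then minimal RTT; positional tie-break.
    """
    if rationale is not None:
        if any(p.pam_disrupted for p in pegs):
            rationale.append("prefer_pam_disrupting_pegrna")
        rationale.append("min_nick_to_edit_distance")
        rationale.append("pbs_near_13_then_min_rtt")
    return sorted(
        pegs,
        key=lambda p: (
            0 if p.pam_disrupted else 1,
            p.nick_to_edit_distance,
            abs(p.pbs_length - 13),
            p.rtt_length,
            *_peg_tiebreak(p),
        ),
    )


def rank_ngrnas(ngs: list[NgRNADesign], rationale=None) -> list[NgRNADesign]:
    """Order nicking guides: PE3b seed > PE3b non-seed > PE3; then nick
    distance closest to 50 bp; then coordinate."""
    ordered = sorted(
        ngs,
        key=lambda g: (
            _CATEGORY_RANK[g.category],
            abs(g.nick_distance - 50),
            g.site.protospacer_interval.start,
        ),
    )
    if rationale is not None and ordered:
        best = ordered[0]
        rationale.append(f"ngrna_category_{best.category}")
        rationale.append("ngrna_distance_near_50")
    return ordered


def recommend(
    spec: EditSpec,
    pegs: list[PegRNADesign],
    ngs_by_peg: dict | None = None,
    params: DesignParams | None = None,
) -> Recommendation:
    """Pick the best pegRNA/ngRNA combination with an explicit rule trace.

    Pure function of its inputs; with an empty design list an untargetable
    Recommendation (pegrna None) is returned rather than raising.
    """
    if not pegs:
        return Recommendation(pegrna=None, ngrna=None, rationale=["untargetable"])
    rationale: list[str] = []
    best_peg = rank_pegrnas(list(pegs), rationale)[0]
    ngs = (ngs_by_peg or {}).get(best_peg, [])
    best_ng = rank_ngrnas(list(ngs), rationale)[0] if ngs else None
    if best_ng is None:
        rationale.append("no_ngrna_in_range")
    return Recommendation(pegrna=best_peg, ngrna=best_ng, rationale=rationale)


def preferred_codons() -> dict[str, str]:
    """Most-used human codon per amino acid from the packaged usage table."""
    rows = _read_packaged_tsv("codon_usage_human_synthetic.tsv")
    best: dict[str, tuple[float, str]] = {}
    for r in rows:
        aa, codon, frac = r["amino_acid"], r["codon"], float(r["fraction"])
        if aa not in best or frac > best[aa][0]:
            best[aa] = (frac, codon)
    return {aa: codon for aa, (_, codon) in best.items()}
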