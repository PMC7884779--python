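"""Nicking sgRNA (ngRNA) enumeration and PE3 / PE3b classification.

The PE3 strategy adds a second sgRNA that nicks the strand opposite the
pegRNA nick.  A PE3b guide is one whose spacer matches the EDITED allele
but mismatches the reference, so the second nick preferentially happens
after the edited-strand flap has resolved.  PE3b guides are further split
by whether any mismatch falls in the seed (PAM-proximal spacer positions
1-10, position 1 adjacent to the PAM) or only outside it.

Binding is therefore evaluated against the edited sequence (a guide whose
PAM only exists post-edit is a legitimate PE3b design) and mismatches are
called against the reference allele.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pegrna_design import (
    NICK_OFFSET,
    PAM_LEN,
    SITE_LEN,
    SPACER_LEN,
    DesignParams,
    PegRNADesign,
    ProtospacerSite,
    _scan_plus,
)
from .sequence_model import DELETED, EditSpec, StrandedInterval, reverse_complement

__all__ = ["NgRNADesign", "enumerate_ngrnas", "classify_pe3b"]

_ACGT = set("ACGT")

PE3 = "PE3"
PE3B_NON_SEED = "PE3b_non_seed"
PE3B_SEED = "PE3b_seed"
SEED_SPAN = 10  # PAM-proximal positions 1-10
DSB_RISK_DISTANCE = 5  # opposing nicks closer than this look like a DSB


def classify_pe3b(mismatch_positions: list[int]) -> str:
    """PE3 / PE3b_seed / PE3b_non_seed from PAM-proximal mismatch positions.

    Positions use PAM-proximal numbering: 1 is the spacer base adjacent to
    the PAM, 20 the 5'-most base.
    """
    for p in mismatch_positions:
        if not 1 <= p <= SPACER_LEN:
            raise ValueError(f"mismatch position {p} outside 1-{SPACER_LEN}")
    if not mismatch_positions:
        return PE3
    if any(p <= SEED_SPAN for p in mismatch_positions):
        return PE3B_SEED
    return PE3B_NON_SEED


@dataclass(frozen=True)
class NgRNADesign:
    """One nicking guide paired with a pegRNA."""

    site: ProtospacerSite  # opposite strand from the peg site; edited-frame seq
    nick_distance: int  # |bp| between the two nicks
    signed_nick_distance: int  # + when the ngRNA nick is 3' of the peg nick
    category: str
    mismatch_positions: tuple  # PAM-proximal numbering, sorted ascending
    overlaps_indel: bool = False
    dsb_risk: bool = False

    def __post_init__(self) -> None:
        assert self.category == classify_pe3b(list(self.mismatch_positions))


def _edited_to_ref_bond(spec: EditSpec, pos: int):
    """Reference bond index for an edited-coordinate bond, or None.

    Bond ``pos`` sits between edited bases ``pos-1`` and ``pos``.  Inserted
    bases have no reference coordinate; the bond is projected to the nearest
    mapped base on its 3' side (flagged upstream via ``overlaps_indel``).
    """
    m = len(spec.edited_sequence)
    for p in range(pos, m):
        r = spec.edited_to_ref(p)
        if r is not None:
            return r
    return len(spec.reference_sequence)


def _reference_window_bases(spec: EditSpec, positions: list[int]):
    """Per edited-coordinate base: the reference base it replaces, or None
    for inserted bases."""
    out = []
    for p in positions:
        r = spec.edited_to_ref(p)
        out.append(None if r is None else spec.reference_sequence[r])
    return out


def enumerate_ngrnas(
    spec: EditSpec,
    peg: PegRNADesign,
    params: DesignParams | None = None,
) -> list[NgRNADesign]:
    """All opposite-strand NGG guides within the nick-distance window.

    Guides are searched on the EDITED sequence (spacer == edited-strand
    window, 5'->3'); each spacer base is projected back onto the reference
    to call mismatches, which drive the PE3 / PE3b classification.  Windows
    containing non-ACGT bases are discarded.  Guides whose window overlaps
    an insertion or deletion junction are classified via edited-coordinate
    projection and flagged ``overlaps_indel``.
    """
    params = params or DesignParams()
    ng_strand = "-" if peg.site.strand == "+" else "+"
    edited = spec.edited_sequence
    m = len(edited)
    ref_len = len(spec.reference_sequence)

    # pegRNA nick bond in reference coordinates
    if peg.site.strand == "+":
        peg_bond = peg.site.nick_position
    else:
        peg_bond = peg.site.nick_position + 1

    # scan the edited sequence in the ngRNA's own + orientation
    search_seq = edited if ng_strand == "+" else reverse_complement(edited)
    lo, hi = params.ngrna_distance_range
    out: list[NgRNADesign] = []
    for i in _scan_plus(search_seq):
        window = search_seq[i : i + SITE_LEN]
        if set(window) - _ACGT:
            continue
        spacer, pam = window[:SPACER_LEN], window[SPACER_LEN:]

        if ng_strand == "+":
            ed_positions = list(range(i, i + SPACER_LEN))  # 5'->3'
            nick_bond_ed = i + NICK_OFFSET
        else:
            ed_start = m - SPACER_LEN - i
            ed_positions = list(range(ed_start + SPACER_LEN - 1, ed_start - 1, -1))
            nick_bond_ed = m - (i + NICK_OFFSET)

        ref_bases = _reference_window_bases(spec, ed_positions)
        if ng_strand == "-":
            ref_bases = [
                None if b is None else reverse_complement(b) for b in ref_bases
            ]
        overlaps_indel = any(b is None for b in ref_bases)
        # a deletion junction inside the window also counts as indel overlap
        mapped = [spec.edited_to_ref(p) for p in ed_positions]
        mapped_only = [r for r in mapped if r is not None]
        if mapped_only:
            span = max(mapped_only) - min(mapped_only) + 1
            if span != len(mapped_only):
                overlaps_indel = True

        mismatch_positions = []
        for idx5, (s_base, r_base) in enumerate(zip(spacer, ref_bases)):
            if r_base is None or s_base != r_base:
                mismatch_positions.append(SPACER_LEN - idx5)  # PAM-proximal
        mismatch_positions.sort()

        # site coordinates on the reference orientation (edited frame coords
        # projected; for pure substitutions these equal reference coords)
        if ng_strand == "+":
            start_ed, end_ed = i, i + SPACER_LEN
        else:
            start_ed, end_ed = m - SPACER_LEN - i, m - i
        site = ProtospacerSite(
            strand=ng_strand,
            spacer=spacer,
            pam=pam,
            protospacer_interval=StrandedInterval(start_ed, end_ed, ng_strand),
            nick_position=(nick_bond_ed if ng_strand == "+" else nick_bond_ed - 1),
        )

        # project the ngRNA nick bond onto reference coordinates
        ref_bond = _edited_to_ref_bond(spec, nick_bond_ed)
        signed = ref_bond - peg_bond
        if peg.site.strand == "-":
            signed = -signed
        if not lo <= abs(signed) <= hi:
            continue
        out.append(
            NgRNADesign(
                site=site,
                nick_distance=abs(signed),
                signed_nick_distance=signed,
                category=classify_pe3b(mismatch_positions),
                mismatch_positions=tuple(mismatch_positions),
                overlaps_indel=overlaps_indel,
                dsb_risk=abs(signed) < DSB_RISK_DISTANCE,
            )
        )
    out.sort(key=lambda g: (g.site.protospacer_interval.start, g.site.strand))
    return out
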