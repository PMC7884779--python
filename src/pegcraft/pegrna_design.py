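"""pegRNA spacer enumeration and 3' extension (RTT + PBS) construction.

Geometry conventions (SpCas9 nickase, NGG PAM):

* A protospacer occupies a 20-nt window immediately 5' of an NGG PAM on the
  protospacer strand.  Spacer positions are numbered 1-20 from the 5' end,
  so position 20 is PAM-adjacent.
* The nick falls between protospacer positions 17 and 18 (3 nt 5' of the
  PAM).  ``nick_position`` is the 0-based offset of the first base 3' of
  the nick on the protospacer strand.
* The PBS is the reverse complement of the ``pbs_length`` reference bases
  immediately 5' of the nick; the RTT is the reverse complement of the
  ``rtt_length`` EDITED-strand bases starting at the nick.  The full 3'
  extension is ``rtt + pbs`` (5'->3').

Minus-strand sites are handled by solving the identical plus-strand problem
on the reverse-complemented :class:`~pegcraft.sequence_model.EditSpec` and
mapping the coordinates back; the extension strings need no mapping because
they are already protospacer-strand sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .sequence_model import (
    DELETED,
    Edit,
    EditSpec,
    StrandedInterval,
    reverse_complement,
)

__all__ = [
    "ProtospacerSite",
    "PegRNADesign",
    "DesignParams",
    "UntargetableReport",
    "find_protospacers",
    "eligible_peg_spacers",
    "build_extension",
    "enumerate_pegrnas",
]

log = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN
NICK_OFFSET = 17  # nick between spacer positions 17|18, 3 nt 5' of the PAM

_ACGT = set("ACGT")


@dataclass(frozen=True)
class ProtospacerSite:
    """One 20-nt spacer + NGG PAM occurrence on the reference."""

    strand: str
    spacer: str
    pam: str
    protospacer_interval: StrandedInterval  # reference coordinates
    nick_position: int  # reference offset of first base 3' of the nick

    def __post_init__(self) -> None:
        if self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} is not NGG")

    @property
    def frame_start(self) -> int:
        """Protospacer start in the site's own (+ strand view) frame.

        For a '+' site this equals the reference start; for a '-' site it is
        the start within the reverse-complemented frame and is recomputed by
        the caller that owns the frame length.
        """
        return self.protospacer_interval.start

    def pam_gg_reference_interval(self) -> StrandedInterval:
        """Reference interval of the PAM's GG dinucleotide (strand-aware)."""
        s, e = self.protospacer_interval.start, self.protospacer_interval.end
        if self.strand == "+":
            return StrandedInterval(e + 1, e + 3, "+")
        return StrandedInterval(s - 3, s - 1, "-")

    def sort_key(self) -> tuple:
        return (self.protospacer_interval.start, 0 if self.strand == "+" else 1)


@dataclass(frozen=True)
class PegRNADesign:
    """One fully specified pegRNA: spacer + 3' extension + annotations."""

    site: ProtospacerSite
    pbs_length: int
    pbs_sequence: str
    rtt_length: int
    rtt_sequence: str
    extension: str
    nick_to_edit_distance: int
    downstream_homology: int
    pam_disrupted: bool = False
    extension_starts_with_C: bool = False
    covers_all_edits: bool = True
    cfd_vs_edited: float | None = None

    def __post_init__(self) -> None:
        assert len(self.extension) == self.pbs_length + self.rtt_length
        assert self.extension == self.rtt_sequence + self.pbs_sequence

    def sort_key(self) -> tuple:
        return (*self.site.sort_key(), self.pbs_length, self.rtt_length)


@dataclass(frozen=True)
class DesignParams:
    """Enumeration ranges and targetability filters.

    Defaults follow the optimised prime-editing parameter ranges: PBS
    10-17 nt, RTT 10-80 nt, nicking-guide distance 0-100 bp, minimum
    downstream homology 5 nt, and a 34-nt RTT ceiling for calling a
    variant targetable.
    """

    pbs_lengths: tuple = tuple(range(10, 18))
    rtt_lengths: tuple = tuple(range(10, 81))
    min_downstream_homology: int = 5
    max_rtt_for_targetability: int = 34
    ngrna_distance_range: tuple = (0, 100)

    def __post_init__(self) -> None:
        if not self.pbs_lengths or not self.rtt_lengths:
            raise ValueError("pbs_lengths and rtt_lengths must be non-empty")
        if min(self.pbs_lengths) <= 0 or min(self.rtt_lengths) <= 0:
            raise ValueError("PBS/RTT lengths must be positive")
        if self.min_downstream_homology < 0 or self.max_rtt_for_targetability <= 0:
            raise ValueError("homology/targetability bounds must be positive")
        lo, hi = self.ngrna_distance_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid ngRNA distance range")

    @property
    def max_rtt(self) -> int:
        return max(self.rtt_lengths)


@dataclass
class UntargetableReport:
    """Structured explanation for an edit with no eligible pegRNA."""

    reasons: list[str] = field(default_factory=list)

    def add(self, reason: str) -> None:
        if reason not in self.reasons:
            self.reasons.append(reason)

    def __bool__(self) -> bool:  # truthy when there ARE reasons
        return bool(self.reasons)


# ---------------------------------------------------------------------------
# spacer search
# ---------------------------------------------------------------------------

def _scan_plus(seq: str):
    """Yield protospacer start offsets of NGG sites on the given strand."""
    for i in range(len(seq) - SITE_LEN + 1):
        if seq[i + SPACER_LEN + 1 : i + SITE_LEN] == "GG":
            yield i


def find_protospacers(seq: str, strand: str = "both") -> list[ProtospacerSite]:
    """All 20-nt spacer + NGG PAM occurrences in ``seq``.

    ``strand`` is '+', '-' or 'both'.  Windows containing characters outside
    ACGT (e.g. N context) are discarded with a warning.  Sites are sorted by
    reference coordinate, then strand ('+' first).
    """
    seq = seq.upper()
    sites: list[ProtospacerSite] = []
    if strand in ("+", "both"):
        for i in _scan_plus(seq):
            window = seq[i : i + SITE_LEN]
            if set(window) - _ACGT:
                log.warning("discarding + strand site at %d: non-ACGT window", i)
                continue
            sites.append(
                ProtospacerSite(
                    strand="+",
                    spacer=window[:SPACER_LEN],
                    pam=window[SPACER_LEN:],
                    protospacer_interval=StrandedInterval(i, i + SPACER_LEN, "+"),
                    nick_position=i + NICK_OFFSET,
                )
            )
    if strand in ("-", "both"):
        rc = reverse_complement(seq)
        n = len(seq)
        for i in _scan_plus(rc):
            window = rc[i : i + SITE_LEN]
            if set(window) - _ACGT:
                log.warning("discarding - strand site: non-ACGT window")
                continue
            # protospacer occupies reference [n-20-i, n-i); nick base maps to
            # reference offset n-1-(i+17)
            start = n - SPACER_LEN - i
            sites.append(
                ProtospacerSite(
                    strand="-",
                    spacer=window[:SPACER_LEN],
                    pam=window[SPACER_LEN:],
                    protospacer_interval=StrandedInterval(start, start + SPACER_LEN, "-"),
                    nick_position=n - 1 - (i + NICK_OFFSET),
                )
            )
    sites.sort(key=ProtospacerSite.sort_key)
    return sites


# ---------------------------------------------------------------------------
# strand frames
# ---------------------------------------------------------------------------

@dataclass
class _Frame:
    """A strand-oriented view of the design problem.

    All geometry is solved in '+' orientation within the frame; ``strand``
    records which reference strand the frame corresponds to so coordinates
    can be mapped back.
    """

    spec: EditSpec
    strand: str
    ref_len: int

    @classmethod
    def for_strand(cls, spec: EditSpec, strand: str) -> "_Frame":
        framed = spec if strand == "+" else spec.reverse_complemented()
        return cls(spec=framed, strand=strand, ref_len=len(spec.reference_sequence))

    def site_to_reference(self, start: int) -> ProtospacerSite:
        """Build a reference-coordinate site from a frame-local spacer start."""
        seq = self.spec.reference_sequence
        window = seq[start : start + SITE_LEN]
        if self.strand == "+":
            interval = StrandedInterval(start, start + SPACER_LEN, "+")
            nick = start + NICK_OFFSET
        else:
            ref_start = self.ref_len - SPACER_LEN - start
            interval = StrandedInterval(ref_start, ref_start + SPACER_LEN, "-")
            nick = self.ref_len - 1 - (start + NICK_OFFSET)
        return ProtospacerSite(
            strand=self.strand,
            spacer=window[:SPACER_LEN],
            pam=window[SPACER_LEN:],
            protospacer_interval=interval,
            nick_position=nick,
        )

    def frame_spacer_start(self, site: ProtospacerSite) -> int:
        if self.strand == "+":
            return site.protospacer_interval.start
        return self.ref_len - site.protospacer_interval.end


def _frames(spec: EditSpec, strand: str = "both"):
    if strand in ("+", "both"):
        yield _Frame.for_strand(spec, "+")
    if strand in ("-", "both"):
        yield _Frame.for_strand(spec, "-")


# ---------------------------------------------------------------------------
# eligibility and extension construction
# ---------------------------------------------------------------------------

def _frame_geometry(frame: _Frame, start: int):
    """(nick, nick_in_edited, edit_start_ed, edit_end_ed) for a frame-local
    spacer start, or None if the nick is not cleanly 5' of every edit."""
    spec = frame.spec
    nick = start + NICK_OFFSET
    span_ref = spec.ref_span()
    if nick > span_ref[0]:
        return None  # nick must lie at/before the first edited reference base
    # No edit touches reference bases 5' of the nick, so the nick bond sits at
    # the same offset in edited coordinates (this also places an insertion at
    # the nick itself at distance 0, 3' of the nick).
    nick_ed = nick
    e_start, e_end = spec.edited_span()
    return nick, nick_ed, e_start, e_end


def eligible_peg_spacers(
    spec: EditSpec,
    params: DesignParams | None = None,
    report: UntargetableReport | None = None,
) -> list[ProtospacerSite]:
    """Sites whose nick is 5' of the edit and within RTT reach.

    A site is kept when (i) its nick lies at or 5' of the first edited base
    on the protospacer strand, (ii) nick-to-edit distance + edited-allele
    span + minimum downstream homology fits within the largest allowed RTT,
    and (iii) the 23-nt spacer/PAM window is intact ACGT reference sequence.
    Both strands are considered.  When nothing qualifies the (optional)
    report collects the reasons instead of raising.
    """
    params = params or DesignParams()
    if not spec.edits:
        raise ValueError("EditSpec contains no edits to install")
    kept: list[ProtospacerSite] = []
    saw_site = False
    for frame in _frames(spec):
        for start in _scan_plus(frame.spec.reference_sequence):
            window = frame.spec.reference_sequence[start : start + SITE_LEN]
            if set(window) - _ACGT:
                continue
            saw_site = True
            geom = _frame_geometry(frame, start)
            if geom is None:
                if report is not None:
                    report.add("nick not 5' of all edited bases")
                continue
            nick, nick_ed, e_start, e_end = geom
            distance = e_start - nick_ed
            span = e_end - e_start
            if distance + span + params.min_downstream_homology > params.max_rtt:
                if report is not None:
                    report.add("edit outside RTT reach")
                continue
            kept.append(frame.site_to_reference(start))
    if not kept and report is not None and not report:
        report.add(
            "no NGG protospacer found" if not saw_site else "no site passed eligibility"
        )
    kept.sort(key=ProtospacerSite.sort_key)
    return kept


def build_extension(
    spec: EditSpec,
    site: ProtospacerSite,
    pbs_length: int,
    rtt_length: int,
    params: DesignParams | None = None,
):
    """Assemble one pegRNA 3' extension, or a rejection reason string.

    Returns a :class:`PegRNADesign` on success and a ``str`` reason on
    rejection (insufficient context, homology below minimum, edit not
    covered, or a non-ACGT window).
    """
    params = params or DesignParams()
    frame = _Frame.for_strand(spec, site.strand)
    return _build_in_frame(frame, site, pbs_length, rtt_length, params)


def _build_in_frame(
    frame: _Frame,
    site: ProtospacerSite,
    pbs_length: int,
    rtt_length: int,
    params: DesignParams,
):
    start = frame.frame_spacer_start(site)
    geom = _frame_geometry(frame, start)
    if geom is None:
        return "nick not 5' of all edited bases"
    nick, nick_ed, e_start, e_end = geom
    fspec = frame.spec

    if nick - pbs_length < 0:
        return "insufficient context for PBS"
    if nick_ed + rtt_length > len(fspec.edited_sequence):
        return "insufficient context for RTT"

    distance = e_start - nick_ed
    span = e_end - e_start
    homology = rtt_length - distance - span
    if nick_ed + rtt_length < e_end:
        return "RTT does not cover all edits"
    if homology < params.min_downstream_homology:
        return f"downstream homology {homology} < {params.min_downstream_homology}"

    pbs_window = fspec.reference_sequence[nick - pbs_length : nick]
    rtt_window = fspec.edited_sequence[nick_ed : nick_ed + rtt_length]
    if set(pbs_window + rtt_window) - _ACGT:
        return "non-ACGT base in PBS/RTT window"

    pbs_seq = reverse_complement(pbs_window)
    rtt_seq = reverse_complement(rtt_window)
    extension = rtt_seq + pbs_seq
    return PegRNADesign(
        site=site,
        pbs_length=pbs_length,
        pbs_sequence=pbs_seq,
        rtt_length=rtt_length,
        rtt_sequence=rtt_seq,
        extension=extension,
        nick_to_edit_distance=distance,
        downstream_homology=homology,
        extension_starts_with_C=extension.startswith("C"),
        covers_all_edits=True,
    )


def enumerate_pegrnas(
    spec: EditSpec,
    params: DesignParams | None = None,
    report: UntargetableReport | None = None,
) -> list[PegRNADesign]:
    """All accepted designs over eligible sites x PBS lengths x RTT lengths.

    Deterministic order: site coordinate, strand ('+' first), PBS, RTT.
    PAM-disruption flags are attached here (annotation is geometric, needing
    only the spec and the site).
    """
    from .annotation_scoring import annotate_pam_disruption  # cycle-free at call time

    params = params or DesignParams()
    designs: list[PegRNADesign] = []
    frames = {s: _Frame.for_strand(spec, s) for s in ("+", "-")}
    for site in eligible_peg_spacers(spec, params, report):
        disrupted = annotate_pam_disruption(spec, site)
        frame = frames[site.strand]
        for pbs in params.pbs_lengths:
            for rtt in params.rtt_lengths:
                built = _build_in_frame(frame, site, pbs, rtt, params)
                if isinstance(built, PegRNADesign):
                    designs.append(replace(built, pam_disrupted=disrupted))
    designs.sort(key=PegRNADesign.sort_key)
    return designs
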