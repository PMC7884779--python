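"""Saturation-mutagenesis edit generation and pooled batch design.

``saturation_edits`` expands a target window into every single-base
substitution (3 per position) or every single-amino-acid substitution
(19 non-reference residues per codon, each encoded with the most-used
human codon).  ``pooled_run`` then designs a pegRNA/ngRNA combination per
edit, reporting untargetable edits with reasons rather than dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_scoring import (
    CFDMatrix,
    CODON_TABLE,
    cfd_vs_edited_allele,
    preferred_codons,
    rank_pegrnas,
    recommend,
)
from .ngrna_design import enumerate_ngrnas
from .pegrna_design import (
    DesignParams,
    UntargetableReport,
    enumerate_pegrnas,
)
from .sequence_model import Edit, EditSpec, StrandedInterval, parse_edit_input

__all__ = ["SaturationJob", "saturation_edits", "pooled_run"]

_BASES = "ACGT"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SaturationJob:
    """A saturation scan over ``target_interval`` of ``context``.

    ``cds_frame_offset`` is the codon phase (0/1/2) of context position 0
    and is required for single_amino_acid mode; the interval must start on
    a codon boundary and span whole codons.
    """

    context: str
    target_interval: StrandedInterval
    mode: str = "single_base"
    cds_frame_offset: int | None = None
    include_stop: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("single_base", "single_amino_acid"):
            raise ValueError(f"unknown saturation mode {self.mode!r}")
        if self.target_interval.end > len(self.context):
            raise ValueError("target_interval extends beyond context")
        if self.mode == "single_amino_acid":
            if self.cds_frame_offset not in (0, 1, 2):
                raise ValueError("single_amino_acid mode requires cds_frame_offset")
            start = self.target_interval.start
            if (start + self.cds_frame_offset) % 3 != 0:
                raise ValueError("target_interval must start on a codon boundary")
            if len(self.target_interval) % 3 != 0:
                raise ValueError("target_interval must span whole codons")


def _edit_string(context: str, edit: Edit) -> str:
    return context[: edit.ref_start] + edit.token() + context[edit.ref_end :]


def saturation_edits(job: SaturationJob) -> list[EditSpec]:
    """All single-base or single-amino-acid edits over the target window.

    single_base: 3 substitutions per position (3·L total).
    single_amino_acid: one edit per non-reference residue per codon,
    encoded with the preferred human codon (19·C for coding codons; stop
    included as a 20th residue only when ``include_stop`` is set).
    """
    context = job.context.upper()
    specs: list[EditSpec] = []
    if job.mode == "single_base":
        for pos in range(job.target_interval.start, job.target_interval.end):
            ref_base = context[pos]
            for alt in _BASES:
                if alt == ref_base:
                    continue
                edit = Edit(ref_start=pos, ref_allele=ref_base, alt_allele=alt)
                specs.append(parse_edit_input(_edit_string(context, edit)))
        return specs

    codons = preferred_codons()
    residues = _AMINO_ACIDS + ("*" if job.include_stop else "")
    for c in range(job.target_interval.start, job.target_interval.end, 3):
        ref_codon = context[c : c + 3]
        ref_aa = CODON_TABLE.get(ref_codon)
        if ref_aa is None:
            raise ValueError(f"non-ACGT codon {ref_codon!r} at {c}")
        for aa in residues:
            if aa == ref_aa:
                continue
            alt_codon = codons[aa]
            changed = [i for i in range(3) if alt_codon[i] != ref_codon[i]]
            lo, hi = min(changed), max(changed)
            edit = Edit(
                ref_start=c + lo,
                ref_allele=ref_codon[lo : hi + 1],
                alt_allele=alt_codon[lo : hi + 1],
            )
            specs.append(parse_edit_input(_edit_string(context, edit)))
    return specs


def design_for_edit(
    spec: EditSpec,
    params: DesignParams | None = None,
    matrix: CFDMatrix | None = None,
    top_k: int = 3,
):
    """Full design for one edit: recommendation, alternatives, reasons.

    Returns (Recommendation, ranked peg designs, UntargetableReport).
    ngRNAs are enumerated per distinct protospacer site (they depend only on
    the nick position) and shared across the site's PBS/RTT grid.
    """
    params = params or DesignParams()
    report = UntargetableReport()
    pegs = enumerate_pegrnas(spec, params, report)
    if matrix is not None:
        from dataclasses import replace

        pegs = [
            replace(p, cfd_vs_edited=cfd_vs_edited_allele(spec, p, matrix))
            for p in pegs
        ]
    ngs_cache: dict = {}
    ngs_by_peg = {}
    for p in pegs:
        key = (p.site.protospacer_interval.start, p.site.strand)
        if key not in ngs_cache:
            ngs_cache[key] = enumerate_ngrnas(spec, p, params)
        ngs_by_peg[p] = ngs_cache[key]
    rec = recommend(spec, pegs, ngs_by_peg, params)
    ranked = rank_pegrnas(pegs) if pegs else []
    return rec, ranked[:top_k], report


def pooled_run(
    edits: list[EditSpec],
    params: DesignParams | None = None,
    matrix: CFDMatrix | None = None,
    top_k: int = 3,
) -> pd.DataFrame:
    """Design a pegRNA/ngRNA combination for every edit in a pooled job.

    One output row per input edit, sorted by edit coordinate (stable);
    untargetable edits keep their row with the failure reasons.  Output is
    deterministic for identical inputs.
    """
    if not edits:
        raise ValueError("pooled_run requires a non-empty edit list")
    params = params or DesignParams()
    rows = []
    order = sorted(range(len(edits)), key=lambda i: (edits[i].ref_span(), i))
    for i in order:
        spec = edits[i]
        rec, alternatives, report = design_for_edit(spec, params, matrix, top_k)
        row = {
            "edit_index": i,
            "edit_input": spec.serialize(),
            "edit_start": spec.ref_span()[0],
            "edit_type": spec.edits[0].edit_type if spec.edits else "none",
            "targetable": rec.targetable,
            "untargetable_reasons": ";".join(report.reasons),
            "rationale": ";".join(rec.rationale),
        }
        if rec.targetable:
            p = rec.pegrna
            row.update(
                spacer=p.site.spacer,
                pam=p.site.pam,
                strand=p.site.strand,
                pbs_length=p.pbs_length,
                rtt_length=p.rtt_length,
                extension=p.extension,
                nick_to_edit_distance=p.nick_to_edit_distance,
                downstream_homology=p.downstream_homology,
                pam_disrupted=p.pam_disrupted,
                cfd_vs_edited=p.cfd_vs_edited,
                alternative_spacers=";".join(
                    sorted({a.site.spacer for a in alternatives})
                ),
            )
            if rec.ngrna is not None:
                row.update(
                    ngrna_spacer=rec.ngrna.site.spacer,
                    ngrna_category=rec.ngrna.category,
                    ngrna_nick_distance=rec.ngrna.nick_distance,
                )
        rows.append(row)
    columns = [
        "edit_index", "edit_input", "edit_start", "edit_type", "targetable",
        "untargetable_reasons", "rationale", "spacer", "pam", "strand",
        "pbs_length", "rtt_length", "extension", "nick_to_edit_distance",
        "downstream_homology", "pam_disrupted", "cfd_vs_edited",
        "alternative_spacers", "ngrna_spacer", "ngrna_category",
        "ngrna_nick_distance",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def oligo_library(
    table: pd.DataFrame,
    scaffold: str = "NNNN",
    adapter5: str = "",
    adapter3: str = "",
) -> list[tuple[str, str]]:
    """(name, oligo) pairs for ordering: 5' adapter + spacer + scaffold
    placeholder + 3' extension + 3' adapter, for targetable rows only."""
    out = []
    for _, row in table.iterrows():
        if not row["targetable"]:
            continue
        oligo = f"{adapter5}{row['spacer']}{scaffold}{row['extension']}{adapter3}"
        out.append((f"edit_{int(row['edit_index'])}", oligo))
    return out
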