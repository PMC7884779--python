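"""ClinVar-style variant batch design and summary statistics.

Reads a variant_summary-style TSV, keeps pathogenic variants with valid
GRCh38 coordinates, expands IUPAC-ambiguous alleles into separate records,
formats edit-encoded inputs for installing or correcting each variant from
flanking genomic sequence, runs the designer under the full parameter sweep
(PBS 10-17, RTT 10-80, ngRNA 0-100 bp), and aggregates targetability and
strategy-availability fractions per variant type.

Targetability follows the published filter: a variant is targetable when at
least one pegRNA spacer admits an accepted design with RTT length < 35 nt
and >= 5 nt of homology downstream of the edit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from pyfaidx import Fasta

from .ngrna_design import PE3B_NON_SEED, PE3B_SEED, enumerate_ngrnas
from .pegrna_design import (
    DesignParams,
    PegRNADesign,
    UntargetableReport,
    enumerate_pegrnas,
)
from .sequence_model import EditSpec, parse_edit_input

__all__ = [
    "VariantRecord",
    "VariantDesignSummary",
    "load_variant_table",
    "variant_to_edit_input",
    "design_variants",
    "summarize_designs",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "Name",
    "RS# (dbSNP)",
    "VariationID",
    "ClinicalSignificance",
    "Assembly",
    "Chromosome",
    "PositionVCF",
    "ReferenceAlleleVCF",
    "AlternateAlleleVCF",
]

_IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class VariantRecord:
    """One variant with VCF-style (1-based, anchored) alleles on GRCh38."""

    variation_id: str
    rs_number: str
    name: str
    chrom: str
    position: int  # 1-based VCF position
    ref_allele: str
    alt_allele: str
    clinical_significance: str

    @property
    def unique_key(self) -> str:
        return f"{self.name}|{self.rs_number}|{self.variation_id}"

    @property
    def edit_type(self) -> str:
        ref, alt, _ = _trim_alleles(self.ref_allele, self.alt_allele)
        if not ref:
            return "insertion"
        if not alt:
            return "deletion"
        if len(ref) == len(alt):
            return "substitution"
        return "complex"


def _trim_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Strip the shared VCF anchor prefix and any shared suffix.

    Returns (trimmed_ref, trimmed_alt, prefix_length).
    """
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    j = 0
    while j < len(ref) - i and j < len(alt) - i and ref[-1 - j] == alt[-1 - j]:
        j += 1
    return ref[i : len(ref) - j], alt[i : len(alt) - j], i


def _expand_iupac(allele: str) -> list[str]:
    options = [""]
    for base in allele:
        choices = _IUPAC_EXPANSION.get(base)
        if choices is None:
            raise ValueError(f"invalid allele base {base!r}")
        options = [o + c for o in options for c in choices]
    return options


def load_variant_table(path) -> list[VariantRecord]:
    """Parse and filter a variant_summary-style TSV.

    Filters: GRCh38 assembly with a valid coordinate; ClinicalSignificance
    exactly "Pathogenic"; unique Name+RS#+VariationID key (duplicates are
    dropped and counted).  IUPAC-ambiguous alleles are expanded into
    separate unambiguous records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing required column(s): {missing}")

    records: list[VariantRecord] = []
    seen: set[str] = set()
    n_dup = n_nonpath = n_badcoord = 0
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        if r["ClinicalSignificance"] != "Pathogenic":
            n_nonpath += 1
            continue
        if r["Assembly"] != "GRCh38":
            n_badcoord += 1
            continue
        try:
            pos = int(r["PositionVCF"])
        except ValueError:
            pos = -1
        if pos <= 0 or not r["Chromosome"]:
            n_badcoord += 1
            continue
        ref_raw = r["ReferenceAlleleVCF"].upper()
        alt_raw = r["AlternateAlleleVCF"].upper()
        if not ref_raw or not alt_raw:
            n_badcoord += 1
            continue
        base = VariantRecord(
            variation_id=r["VariationID"],
            rs_number=r["RS# (dbSNP)"],
            name=r["Name"],
            chrom=r["Chromosome"],
            position=pos,
            ref_allele=ref_raw,
            alt_allele=alt_raw,
            clinical_significance=r["ClinicalSignificance"],
        )
        if base.unique_key in seen:
            n_dup += 1
            continue
        seen.add(base.unique_key)
        for ref in _expand_iupac(ref_raw):
            for alt in _expand_iupac(alt_raw):
                if ref == alt:
                    continue
                records.append(
                    VariantRecord(
                        variation_id=base.variation_id,
                        rs_number=base.rs_number,
                        name=base.name,
                        chrom=base.chrom,
                        position=base.position,
                        ref_allele=ref,
                        alt_allele=alt,
                        clinical_significance=base.clinical_significance,
                    )
                )
    log.info(
        "variant table: kept %d record(s); dropped %d non-pathogenic, "
        "%d without valid GRCh38 coordinate, %d duplicate key(s)",
        len(records), n_nonpath, n_badcoord, n_dup,
    )
    return records


def variant_to_edit_input(
    rec: VariantRecord, flank: str, flank_start: int, direction: str = "install"
) -> str:
    """Edit-encoded string for installing or correcting one variant.

    ``flank`` is reference sequence starting at 1-based genomic coordinate
    ``flank_start``.  install: token (REF/ALT) in the reference flank;
    correct: the variant is first applied to the flank and the token swaps
    the alleles back.  A disagreement between the flank and the reference
    allele is a hard error.
    """
    if direction not in ("install", "correct"):
        raise ValueError(f"direction must be install or correct, got {direction!r}")
    flank = flank.upper()
    offset = rec.position - flank_start  # 0-based offset of the VCF anchor base
    ref, alt, prefix = _trim_alleles(rec.ref_allele, rec.alt_allele)
    start = offset + prefix
    if offset < 0 or offset + len(rec.ref_allele) > len(flank):
        raise ValueError("flank does not cover the variant")
    observed = flank[offset : offset + len(rec.ref_allele)]
    if observed != rec.ref_allele:
        raise ValueError(
            f"reference mismatch at {rec.chrom}:{rec.position}: flank has "
            f"{observed!r}, variant table says {rec.ref_allele!r}"
        )

    if direction == "install":
        left, right = flank[:start], flank[start + len(ref):]
        token_ref, token_alt = ref, alt
    else:
        # apply the variant to the flank, then encode the inverse edit
        edited_flank = flank[:start] + alt + flank[start + len(ref):]
        left, right = edited_flank[:start], edited_flank[start + len(alt):]
        token_ref, token_alt = alt, ref

    if not token_ref and token_alt:
        token = f"(+{token_alt})"
    elif token_ref and not token_alt:
        token = f"(-{token_ref})"
    else:
        token = f"({token_ref}/{token_alt})"
    return left + token + right


@dataclass
class VariantDesign:
    """Designs for one variant in one direction."""

    record: VariantRecord
    edit_input: str
    spec: EditSpec | None
    pegs: list[PegRNADesign]
    ngrna_categories: set
    report: UntargetableReport
    error: str | None = None

    def qualifying_pegs(self, params: DesignParams) -> list[PegRNADesign]:
        """Designs meeting the targetability filter (RTT <= 34, homology >= 5)."""
        return [
            p
            for p in self.pegs
            if p.rtt_length <= params.max_rtt_for_targetability
            and p.downstream_homology >= params.min_downstream_homology
        ]


def design_variants(
    records: list[VariantRecord],
    genome_fasta,
    params: DesignParams | None = None,
    direction: str = "correct",
    flank_size: int = 100,
) -> list[VariantDesign]:
    """Run the full designer on every variant with flanks from a FASTA.

    Reference-mismatch variants are reported (``error`` set), never silently
    skipped.  ngRNA categories are collected per distinct protospacer site
    of the qualifying designs.
    """
    params = params or DesignParams()
    genome = Fasta(str(genome_fasta)) if not isinstance(genome_fasta, Fasta) else genome_fasta
    out: list[VariantDesign] = []
    for rec in records:
        flank_start = max(1, rec.position - flank_size)
        flank_end = rec.position + len(rec.ref_allele) - 1 + flank_size
        try:
            flank = str(genome[rec.chrom][flank_start - 1 : flank_end])
            edit_input = variant_to_edit_input(rec, flank, flank_start, direction)
        except (KeyError, ValueError) as exc:
            log.warning("variant %s skipped: %s", rec.unique_key, exc)
            out.append(
                VariantDesign(rec, "", None, [], set(),
                              UntargetableReport(), error=str(exc))
            )
            continue
        spec = parse_edit_input(edit_input)
        report = UntargetableReport()
        pegs = enumerate_pegrnas(spec, params, report)
        categories: set = set()
        seen_sites: set = set()
        for p in pegs:
            if (
                p.rtt_length > params.max_rtt_for_targetability
                or p.downstream_homology < params.min_downstream_homology
            ):
                continue
            key = (p.site.protospacer_interval.start, p.site.strand)
            if key in seen_sites:
                continue
            seen_sites.add(key)
            for g in enumerate_ngrnas(spec, p, params):
                categories.add(g.category)
        out.append(VariantDesign(rec, edit_input, spec, pegs, categories, report))
    return out


@dataclass
class VariantDesignSummary:
    """Targetability and strategy-availability fractions, overall and per
    variant type."""

    n_total: int
    n_targetable: int
    mean_spacers_per_targetable: float
    mean_spacers_per_variant: float
    frac_targetable: float
    frac_pam_disrupting: float  # among targetable
    frac_pe3b_any: float  # among targetable
    frac_pe3b_seed: float  # among targetable
    frac_both_pam_and_seed: float  # among targetable
    by_type: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "by_type"}
        d["by_type"] = self.by_type
        return d


def _summary_block(designs: list[VariantDesign], params: DesignParams) -> dict:
    n_total = len(designs)
    spacer_counts = []
    targetable = []
    for d in designs:
        qual = d.qualifying_pegs(params)
        sites = {(p.site.protospacer_interval.start, p.site.strand) for p in qual}
        spacer_counts.append(len(sites))
        if sites:
            targetable.append((d, qual))
    n_targetable = len(targetable)
    n_pam = sum(
        1 for d, qual in targetable if any(p.pam_disrupted for p in qual)
    )
    n_pe3b = sum(
        1
        for d, _ in targetable
        if d.ngrna_categories & {PE3B_SEED, PE3B_NON_SEED}
    )
    n_seed = sum(1 for d, _ in targetable if PE3B_SEED in d.ngrna_categories)
    n_both = sum(
        1
        for d, qual in targetable
        if PE3B_SEED in d.ngrna_categories and any(p.pam_disrupted for p in qual)
    )
    per_targetable = [c for c in spacer_counts if c > 0]
    return {
        "n_total": n_total,
        "n_targetable": n_targetable,
        "mean_spacers_per_targetable": (
            sum(per_targetable) / n_targetable if n_targetable else 0.0
        ),
        "mean_spacers_per_variant": (
            sum(spacer_counts) / n_total if n_total else 0.0
        ),
        "frac_targetable": n_targetable / n_total if n_total else 0.0,
        "frac_pam_disrupting": n_pam / n_targetable if n_targetable else 0.0,
        "frac_pe3b_any": n_pe3b / n_targetable if n_targetable else 0.0,
        "frac_pe3b_seed": n_seed / n_targetable if n_targetable else 0.0,
        "frac_both_pam_and_seed": n_both / n_targetable if n_targetable else 0.0,
    }


def summarize_designs(
    designs: list[VariantDesign], params: DesignParams | None = None
) -> VariantDesignSummary:
    """Aggregate per-variant designs into the summary fractions.

    Spacers per variant counts DISTINCT protospacer sites among designs
    passing the targetability filter, not PBS/RTT grid points; strategy
    fractions are computed among targetable variants only.  Strata follow
    the substitution/insertion/deletion/complex edit taxonomy.
    """
    params = params or DesignParams()
    overall = _summary_block(designs, params)
    by_type = {}
    for etype in ("substitution", "insertion", "deletion", "complex"):
        sub = [d for d in designs if d.record.edit_type == etype]
        if sub:
            by_type[etype] = _summary_block(sub, params)
    return VariantDesignSummary(by_type=by_type, **overall)
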