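"""Deterministic synthetic fixtures: random loci, a mini-genome and a
variant panel, for offline testing of the whole design pipeline.

Everything is seeded; the same seed reproduces a byte-identical bundle.
Expected protospacer counts in the manifest are computed by a deliberately
naive scan kept independent of the design modules, so pipeline/oracle
agreement is a meaningful check.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["FixtureBundle", "random_locus", "generate_fixtures", "write_bundle"]

_BASES = "ACGT"
EDIT_TYPES = ("substitution", "insertion", "deletion", "complex")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _naive_protospacer_count(seq: str) -> int:
    """Independent double-strand NGG window count (no shared design code)."""
    n = 0
    for i in range(len(seq) - 22):
        if seq[i + 21] == "G" and seq[i + 22] == "G":  # + strand NGG
            n += 1
        if seq[i] == "C" and seq[i + 1] == "C":  # - strand NGG (CCN on +)
            n += 1
    return n


def random_locus(
    rng: random.Random,
    length: int = 300,
    edit_type: str | None = None,
    plant_pam: bool = True,
) -> str:
    """One edit-encoded locus with a random edit of the requested type.

    With ``plant_pam`` a + strand NGG is placed so that its nick falls a few
    bases 5' of the edit, guaranteeing at least one eligible spacer; random
    sequence supplies additional incidental sites on both strands.
    """
    edit_type = edit_type or rng.choice(EDIT_TYPES)
    seq = list(_random_seq(rng, length))
    pos = rng.randrange(length // 2 - 10, length // 2 + 10)
    if plant_pam:
        # place PAM so the nick (3 nt 5' of the PAM) sits 0-8 nt 5' of the edit
        nick = pos - rng.randrange(0, 9)
        pam_start = nick + 3
        if 20 <= nick and pam_start + 3 <= length:
            seq[pam_start + 1] = "G"
            seq[pam_start + 2] = "G"
    ref = "".join(seq)
    if edit_type == "substitution":
        alt = rng.choice([b for b in _BASES if b != ref[pos]])
        token = f"({ref[pos]}/{alt})"
        return ref[:pos] + token + ref[pos + 1 :]
    if edit_type == "insertion":
        ins = _random_seq(rng, rng.randrange(1, 6))
        return ref[:pos] + f"(+{ins})" + ref[pos:]
    if edit_type == "deletion":
        span = rng.randrange(1, 6)
        return ref[:pos] + f"(-{ref[pos:pos + span]})" + ref[pos + span :]
    # complex: replace a short window with a different-length random string
    span = rng.randrange(2, 5)
    old = ref[pos : pos + span]
    new = old
    while new == old:
        new = _random_seq(rng, rng.randrange(1, 6))
    return ref[:pos] + f"({old}/{new})" + ref[pos + span :]


@dataclass
class FixtureBundle:
    """Synthetic loci + mini-genome + variant panel + count manifest."""

    seed: int
    loci: list[str]
    genome: dict  # contig name -> sequence
    variant_rows: list[dict]
    manifest: dict = field(default_factory=dict)


def _variant_row(name, rs, vid, sig, assembly, chrom, pos, ref, alt):
    return {
        "Name": name,
        "RS# (dbSNP)": rs,
        "VariationID": vid,
        "ClinicalSignificance": sig,
        "Assembly": assembly,
        "Chromosome": chrom,
        "PositionVCF": str(pos),
        "ReferenceAlleleVCF": ref,
        "AlternateAlleleVCF": alt,
    }


def generate_fixtures(seed: int, n_loci: int = 12) -> FixtureBundle:
    """Build the full deterministic fixture bundle for one seed.

    The variant panel contains pathogenic SNVs, an insertion, a deletion,
    an IUPAC-ambiguous allele (expanded downstream), plus records that the
    loader must drop: a "Likely pathogenic" significance, a GRCh37-only
    coordinate, and a duplicate unique key.
    """
    rng = random.Random(seed)
    loci = [
        random_locus(rng, rng.randrange(250, 400), EDIT_TYPES[i % 4])
        for i in range(n_loci)
    ]
    genome = {
        "chr1": _random_seq(rng, 3000),
        "chr2": _random_seq(rng, 2500),
    }

    rows = []
    vid = 1000
    for chrom, n_snv in (("chr1", 5), ("chr2", 3)):
        seq = genome[chrom]
        for _ in range(n_snv):
            pos = rng.randrange(300, len(seq) - 300)
            ref = seq[pos - 1]  # VCF 1-based
            alt = rng.choice([b for b in _BASES if b != ref])
            vid += 1
            rows.append(
                _variant_row(
                    f"NM_{vid}.1:c.{pos}{ref}>{alt}", f"rs{vid}", str(vid),
                    "Pathogenic", "GRCh38", chrom, pos, ref, alt,
                )
            )
    # anchored insertion and deletion on chr1
    seq = genome["chr1"]
    pos = rng.randrange(400, 2000)
    vid += 1
    rows.append(
        _variant_row(
            f"NM_{vid}.1:c.{pos}ins", f"rs{vid}", str(vid), "Pathogenic",
            "GRCh38", "chr1", pos, seq[pos - 1], seq[pos - 1] + _random_seq(rng, 3),
        )
    )
    pos = rng.randrange(400, 2000)
    vid += 1
    rows.append(
        _variant_row(
            f"NM_{vid}.1:c.{pos}del", f"rs{vid}", str(vid), "Pathogenic",
            "GRCh38", "chr1", pos, seq[pos - 1 : pos + 3], seq[pos - 1],
        )
    )
    # ambiguous alt allele (R -> A/G)
    pos = rng.randrange(400, 2000)
    while seq[pos - 1] in "AG":
        pos += 1
    vid += 1
    rows.append(
        _variant_row(
            f"NM_{vid}.1:c.{pos}amb", f"rs{vid}", str(vid), "Pathogenic",
            "GRCh38", "chr1", pos, seq[pos - 1], "R",
        )
    )
    # records the loader must drop
    rows.append(
        _variant_row(
            "NM_drop.1:c.1A>G", "rs1", "9001", "Likely pathogenic",
            "GRCh38", "chr1", 500, seq[499], "G" if seq[499] != "G" else "A",
        )
    )
    rows.append(
        _variant_row(
            "NM_drop.2:c.2C>T", "rs2", "9002", "Pathogenic",
            "GRCh37", "chr1", 600, seq[599], "T" if seq[599] != "T" else "C",
        )
    )
    rows.append(dict(rows[0]))  # duplicate unique key

    manifest = {
        "seed": seed,
        "n_loci": n_loci,
        "locus_protospacer_counts": [
            _naive_protospacer_count(_reference_of(locus)) for locus in loci
        ],
        "n_variant_rows": len(rows),
    }
    return FixtureBundle(
        seed=seed, loci=loci, genome=genome, variant_rows=rows, manifest=manifest
    )


def _reference_of(locus: str) -> str:
    """Reference sequence of an edit-encoded string, by naive token surgery
    (independent of the grammar module)."""
    out, i = [], 0
    while i < len(locus):
        c = locus[i]
        if c == "(":
            j = locus.index(")", i)
            body = locus[i + 1 : j]
            if body.startswith("+"):
                pass
            elif body.startswith("-"):
                out.append(body[1:])
            else:
                out.append(body.split("/")[0])
            i = j + 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def write_bundle(bundle: FixtureBundle, outdir) -> dict:
    """Write the bundle as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci_path = outdir / "loci.txt"
    loci_path.write_text("\n".join(bundle.loci) + "\n")
    genome_path = outdir / "mini_genome.fa"
    with genome_path.open("w") as fh:
        for name, seq in bundle.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    variants_path = outdir / "variants.tsv"
    cols = list(bundle.variant_rows[0].keys())
    with variants_path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in bundle.variant_rows:
            fh.write("\t".join(row[c] for c in cols) + "\n")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2) + "\n")
    return {
        "loci": str(loci_path),
        "genome": str(genome_path),
        "variants": str(variants_path),
        "manifest": str(manifest_path),
    }
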