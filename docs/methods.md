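# Methods

## Design model

`pegcraft` models SpCas9-nickase prime editing with fixed geometry: a
protospacer is a 20-nt window immediately 5′ of an NGG PAM, and the nick
falls between protospacer positions 17 and 18 (3 nt 5′ of the PAM).  All
design logic is solved in a "+ strand frame"; minus-strand sites are handled
by reverse-complementing the whole edit specification (reference, edited
sequence and edit coordinates), solving the identical plus-strand problem,
and mapping coordinates back.  Extension sequences need no mapping because
they are protospacer-strand sequences by construction.

A candidate site is eligible when

1. its nick lies at or 5′ of the first edited base on the protospacer
   strand (the PBS and everything 5′ of the nick must be unedited, so the
   pegRNA engages pre-edit DNA);
2. nick-to-edit distance + edited-allele span + minimum downstream homology
   fits inside the largest allowed RTT; and
3. the 23-nt spacer/PAM window is intact ACGT sequence in the reference.

For combination edits the RTT must cover **all** edits plus the homology
margin; designs covering a subset are rejected.  Because every edit lies 3′
of the nick, the nick's offset is identical in reference and edited
coordinates, which keeps PBS windows (reference) and RTT windows (edited
allele) consistent without special-casing insertions at the nick.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| PBS lengths | 10–17 | nt | optimised prime-editing range; 13 is used as the "typical" target in ranking |
| RTT lengths | 10–80 | nt | full enumeration range for design tables |
| min downstream homology | 5 | nt | flap must re-anneal 3′ of the edit |
| RTT ceiling for targetability | 34 | nt | "targetable" means ≥1 accepted design with RTT < 35 nt |
| ngRNA nick distance | 0–100 | bp | opposite-strand nicking window |

The targetability ceiling (34) is deliberately separate from the
enumeration maximum (80): variant tables are swept across the full range,
but a variant only counts as targetable if a < 35 nt RTT design exists.
Opposing nicks closer than 5 bp are kept but flagged `dsb_risk`; nick
distance 0 (a plain double-strand break) is therefore never silently
recommended.

## ngRNA classification

Nicking guides are searched on the **edited** sequence (a guide whose PAM
only exists after editing is a legitimate PE3b design; a guide whose PAM the
edit destroys is dropped).  Each spacer base is projected back onto the
reference through the per-base coordinate map; mismatches are reported in
PAM-proximal numbering (position 1 adjacent to the PAM).  No mismatch →
PE3; any mismatch in positions 1–10 → PE3b seed; otherwise PE3b non-seed.
Guides overlapping insertions or deletion junctions are classified through
the same projection (inserted bases count as mismatches, since the
reference offers no base to pair) and flagged `overlaps_indel`; nick
distances for such guides use the nearest mapped base 3′ of the nick bond.

## Ranking

The recommendation is a deterministic rule cascade, each rule logged in the
returned rationale: (1) prefer PAM-disrupting pegRNAs; (2) smaller
nick-to-edit distance; (3) PBS closest to 13 nt, then the minimal RTT
satisfying the homology margin; ties broken by coordinate, then + strand.
For the ngRNA: PE3b seed > PE3b non-seed > PE3, then nick distance closest
to 50 bp, then coordinate.  The same ordering ranks the alternatives
reported in pooled mode.

## CFD scoring

The CFD score multiplies per-position mismatch penalties and a PAM-tail
penalty.  It is computed for the pegRNA spacer against the **edited allele
at its own locus** — a proxy for unwanted re-engagement after successful
editing — not a genome-wide off-target search, which is out of scope.  The
packaged penalty tables are synthetic stand-ins with the published schema
(per spacer-base/target-base/position factor in [0,1]; GG PAM tail → 1.0)
and a plausible structure: PAM-proximal mismatches penalised harder,
wobble-like pairs milder.  All properties the package relies on (perfect
match scores 1.0, multiplicative monotonicity, single mismatch = direct
lookup) hold for any valid table, and `load_cfd_matrix` accepts replacement
TSVs for users who want the published values.

## Silent PAM disruptors

Synonymous alternatives are enumerated for the codon(s) overlapping the
PAM's GG dinucleotide only, under the standard genetic code (stop codons
are never rewritten).  The caller supplies the codon phase of context
position 0 and the CDS strand; minus-strand CDS is handled by frame
flipping.  A proposal survives only if it changes ≥ 1 GG base, does not
collide with the user's edits, and leaves the combined edit set within RTT
reach of the same site.  Note that when the GG occupies the first two bases
of a glycine codon no disruptor exists (all Gly codons share the GG), a
geometric fact the tests pin down.

## Saturation and variant batch modes

Single-base mode emits the 3 non-reference substitutions per position
(3·L edits); single-amino-acid mode emits one edit per non-reference
residue per codon, encoded with the most-used human codon from the packaged
usage table (19·C for coding codons; if a window codon is a stop, all 20
residues are non-reference and the per-codon count is 20; stop-as-residue
is available behind `include_stop`, default off).

Variant batch mode reads a ClinVar-style `variant_summary` TSV, keeps rows
with a valid GRCh38 coordinate and ClinicalSignificance exactly
"Pathogenic", dedups on the Name + RS# + VariationID key, and expands
IUPAC-ambiguous alleles into separate unambiguous records.  Edit inputs are
formatted from ±100 bp flanks (default) pulled from an indexed FASTA;
"install" places `(REF/ALT)` in the reference flank, "correct" applies the
variant first and swaps the token.  A flank/allele disagreement is a hard,
logged error.  Summary statistics count **distinct spacers** (not PBS/RTT
grid points) per variant, call a variant targetable when ≥ 1 design passes
the RTT ≤ 34 / homology ≥ 5 filter, and compute PAM-disruption and PE3b
availability among targetable variants, overall and per edit type.

## Synthetic fixtures and what they show

The fixture generator plants a + strand PAM a few bases 5′ of each random
locus's edit, guaranteeing at least one eligible site, and otherwise uses
uniform random sequence, so incidental PAMs on both strands appear at
natural density.  The mini-genome (two contigs, 3 kb and 2.5 kb) and the
12-variant panel exercise SNVs, anchored indels, IUPAC expansion and the
loader's drop rules.  Passing tests therefore demonstrate the
*combinatorial correctness* of enumeration, construction, classification
and accounting — not wet-lab editing efficiency, and not the statistics of
any real ClinVar snapshot, which depend on the genome-wide PAM landscape
around real pathogenic variants.

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open internally; 1-based inclusive in output
  tables.  Interval validity is enforced at construction.
* Windows containing non-ACGT bases (N context) are discarded with a
  logged warning, never silently scored.
* Insertions count as PAM-disrupting only when the junction splits the two
  Gs; an insertion 5′ of the PAM shifts but does not mutate the motif.
* Ambiguous IUPAC codes are rejected inside edit tokens (expansion is a
  variant-table concern) but tolerated in flanking context.
* `enumerate_pegrnas` output order is (site coordinate, strand, PBS, RTT);
  identical inputs give byte-identical tables.
* Problem sizes used by the test suite and `scripts/acceptance.py` —
  ~200 loci of 200–500 nt and a 12-variant panel under the full PBS/RTT/ng
  sweep — were chosen to exercise every edit type and both strands while
  keeping a laptop run in the order of a minute.

## Known limitations

* SpCas9 NGG geometry only; no alternative PAMs or nickases.
* No machine-learned efficiency prediction, no RNA secondary structure, no
  genome-wide off-target enumeration.
* The CFD and codon-usage tables are synthetic stand-ins (see above);
  swap in published tables via the loader arguments for production use.
* HGVS strings in variant names are carried as identifiers, not parsed.
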