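# pegcraft

Prime editing installs precise edits — substitutions, insertions, deletions
and combinations of them — using a Cas9-H840A nickase fused to a reverse
transcriptase, directed by a **pegRNA** (prime editing guide RNA).  Designing
a working pegRNA by hand is fiddly: the spacer must place the nick 5′ of the
edit, the 3′ extension must combine a primer binding site (PBS) annealing to
the nicked strand with a reverse transcription template (RTT) that encodes
the edit plus downstream homology, and a secondary nicking sgRNA (**ngRNA**,
the PE3/PE3b strategies) needs its own opposite-strand protospacer.

`pegcraft` automates this for bench scientists and screen builders.  From a
single sequence that encodes both the reference and the edited allele it:

* enumerates every SpCas9 NGG protospacer on both strands and keeps the
  sites whose nick (between protospacer positions 17/18, 3 nt 5′ of the PAM)
  lies 5′ of the edit and within RTT reach;
* builds every 3′ extension over the optimised parameter ranges
  (PBS 10–17 nt, RTT 10–80 nt), rejecting windows that fail the minimum
  downstream homology (5 nt) or run off the provided context;
* enumerates opposite-strand ngRNAs within 0–100 bp of the pegRNA nick and
  classifies them PE3 / PE3b non-seed / PE3b seed (a mismatch to the
  unedited allele within PAM-proximal spacer positions 1–10);
* annotates PAM disruption (edits hitting the GG of the NGG), proposes
  synonymous PAM-disrupting mutations inside coding frames, scores spacers
  against the edited allele with a multiplicative CFD-style penalty model,
  and recommends a pegRNA/ngRNA combination with an explicit rule trace;
* scales to saturation-mutagenesis libraries (every single-base or
  single-amino-acid variant over a window) and to ClinVar-style variant
  tables (install or correct, with per-type targetability statistics).

## The edit-encoding grammar

One string carries both alleles.  Plain bases are shared context; tokens
describe edits:

| token      | meaning                        | example                  |
|------------|--------------------------------|--------------------------|
| `(REF/ALT)`| substitution / replacement     | `ATGC(A/T)GGCC`          |
| `(+SEQ)`   | insertion                      | `ATGC(+TT)GGCC`          |
| `(-SEQ)`   | deletion                       | `AT(-GC)GCAT`            |

For an accepted design on a site with nick offset *n* (0-based, protospacer
strand), the extension is assembled 5′→3′ as

```
extension = revcomp(edited[n : n + RTT]) + revcomp(reference[n - PBS : n])
          =        RTT sequence          +        PBS sequence
```

and the reverse-transcribed flap `revcomp(extension)[PBS:]` rebuilds the
edited allele exactly over the RTT window — an invariant the test suite
checks for every accepted design.

## Worked example

```
$ pegcraft design "AAAACCCCGGGGTTTTAACCTGGA(C/A)GTACGTACCATTACGGCCAGTA" --out demo.csv
recommended pegRNA: spacer AAAACCCCGGGGTTTTAACC (+) PBS 13 RTT 13
recommended ngRNA: CCGTAATGGTACGTACTTCC [PE3b_seed, nick distance 7]
rationale: min_nick_to_edit_distance, pbs_near_13_then_min_rtt, ngrna_category_PE3b_seed, ngrna_distance_near_50
576 design rows written to demo.csv
```

The input places a C→A substitution 7 nt 3′ of the nick of the + strand
protospacer `AAAACCCCGGGGTTTTAACC` (PAM `TGG`).  The recommended design uses
a 13-nt PBS and the minimal 13-nt RTT that still leaves 5 nt of homology
downstream of the edit; its extension is
`CGTACTTCCAGGT`+`TAAAACCCCGGGG` (RTT + PBS).  The chosen ngRNA overlaps the
edited base at a seed position, so it nicks the opposite strand only after
the edit has resolved (PE3b seed).  `demo.csv` holds one row per
(pegRNA, ngRNA) pair with 1-based coordinates, annotations and CFD scores;
`demo.meta.json` records the version, parameters and input hash.

Other subcommands: `pegcraft pooled` (saturation libraries + oligo FASTA),
`pegcraft variants` (variant-table batch design + summary JSON),
`pegcraft fixtures` (the seeded synthetic test bundle).  Everything is also
available as a library: `pegcraft.parse_edit_input`,
`pegcraft.enumerate_pegrnas`, `pegcraft.enumerate_ngrnas`,
`pegcraft.recommend`, `pegcraft.saturation_edits`, `pegcraft.pooled_run`,
`pegcraft.design_variants`, `pegcraft.summarize_designs`.

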