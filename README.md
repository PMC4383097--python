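# ampliquant

Quantitation of CRISPR-Cas9 genome-editing outcomes at amplicon loci, for
researchers measuring how efficiently a Cas9 ribonucleoprotein cuts a target
and how often the break is repaired from a donor template.

Two complementary readouts are implemented:

1. **Amplicon deep sequencing.** Paired-end reads spanning the target are
   quality-filtered (any base below Q30 removes the read after 3' windowed
   trimming), pooled in a common orientation (R1 plus reverse-complemented
   R2), and each read is locally aligned (affine-gap Smith-Waterman) against
   a 53-nt reference window — the 20-nt protospacer, 3-nt PAM and 15 nt of
   flanking sequence on each side, centred on the blunt cut site 3 bp
   upstream of the PAM. Reads whose alignment covers the full window are
   classified: gapless → unedited; gapped → indel; gapped and carrying the
   locus-specific diagnostic insert (e.g. `AAGCTTGCTAGC`, a
   HindIII+NheI cassette) → homology-directed repair (HDR). Frequencies over
   informative reads:

   ```
   TE%     = 100 · (#NHEJ + #HDR indel reads) / (#indel + #non-indel reads)
   HDR%    = 100 · #HDR reads / (#indel + #non-indel reads)
   HDR/TE% = 100 · HDR% / TE%
   ```

   TE (total editing) counts HDR events because the templated insertion
   itself produces an alignment gap.

2. **Gel densitometry.** From band intensities `a` (uncleaved substrate)
   and `b`, `c` (cleavage products), with f = (b+c)/(a+b+c):
   T7 endonuclease I total editing `TE% = (1 − √(1 − f)) · 100` — the square
   root corrects for random strand re-annealing, where one edited duplex
   yields two cleavable heteroduplexes — and restriction-digest (RFLP) HDR
   `HDR% = f · 100`, since the enzyme cuts edited alleles directly. A
   Monte-Carlo re-annealing simulator verifies the correction exactly
   inverts random pairing.

A synthetic-data module generates paired-end FASTQ from a configurable
mixture of wild-type, NHEJ-indel and HDR alleles with per-base errors and a
ground-truth table, so every pipeline stage is testable without external
data.

## Worked example

Write a locus config (`loci.yaml`) with the protospacer, PAM, amplicon and
expected HDR insert, then:

```bash
ampliquant simulate --loci loci.yaml -n 5000 --frac-hdr 0.2 --frac-nhej 0.15 \
    --seed 11 -o .
ampliquant quantify --r1 synthetic_example_R1.fastq \
    --r2 synthetic_example_R2.fastq --loci loci.yaml -o demo
```

prints

```json
{
  "hdr_over_te_pct": 53.9766,
  "hdr_pct": 18.6729,
  "n_filtered": 4957,
  "n_indel_hdr": 923,
  "n_indel_nhej": 787,
  "n_informative": 4943,
  "n_non_indel": 3233,
  "te_pct": 34.5944
}
```

The simulation mixed 15% NHEJ and 20% HDR alleles; the pipeline recovers
TE ≈ 34.6% (vs 35% configured) and HDR ≈ 18.7% from the 4,943 informative
reads. The 4,957 filtered reads are the R2 mates: on a 640-nt amplicon,
300-nt reads reach the target window from one side only, so the far-side
mates cannot cover the full window and are excluded from every denominator.
Sampling noise at this depth is ±1–2 percentage points.

Gel band intensities are analysed from a TSV
(`sample  assay  a  b  c`, assay ∈ {t7e1, rflp}):

```bash
$ ampliquant gel -i bands.tsv
sample assay  estimate_pct
  ctrl  t7e1        9.4461
   noc  t7e1       50.0000
   noc  rflp       30.0000
```

A 75%-cleaved T7E1 lane (25/40/35) is 50% editing after the re-annealing
correction, not 75%.

Other subcommands: `preprocess` (filter + pool to FASTA), `align` (per-read
alignment dump), `run` (full multi-sample pipeline from a YAML config,
deterministic under its seed), `compare` (deltas and fold-changes between
two run summaries).

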