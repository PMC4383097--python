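# Methods

## Locus model and coordinates

A target is a 20-nt protospacer with a 3-nt PAM, embedded exactly once (on a
declared strand) in the PCR amplicon. All coordinates are 0-based and
half-open; cut sites are inter-base indices, which makes insert placement
unambiguous. Cas9 is modelled as a blunt cutter 3 bp 5' of the PAM, i.e. at
inter-base index `protospacer_start + 17` on the protospacer strand; for
minus-strand targets the index is mapped back into plus-strand amplicon
coordinates as `len(amplicon) − cut`. Non-NGG PAMs raise a warning, not an
error, so off-target windows with degenerate PAMs can still be quantified.

The classification reference window is `flank + protospacer + PAM + flank`
(53 nt at the default `flank=15`), reported in protospacer-strand
orientation. That fixed frame is what makes the HDR key comparison
well-defined: the diagnostic insert is stored in window frame, and inserts
declared in amplicon plus-strand frame are reverse-complemented for
minus-strand loci. (Consistently, a locus read off the opposite genomic
strand carries the reverse-complemented key.)

Donor templates are declared as `left arm | insert | right arm`, with an
optional deletion immediately 3' of the cut. Validation reconstructs the
edited allele and requires both arms to match the amplicon base-for-base,
reporting the first mismatch position; minus-orientation templates
(single-stranded donors complementary to the target strand) are normalised
by reverse complement before comparison.

## Read simulator

The generator models the editing experiment the quantitation assumes: each
read pair derives from one allele drawn as wild-type, NHEJ-edited or
HDR-edited with configured probabilities. Defaults are the study conditions
the pipeline is meant for — 300-nt paired-end reads from a ~640-nt amplicon,
20,000 pairs, 15% NHEJ / 20% HDR where a mixture is needed, and 0.1%
per-base substitution error.

* **NHEJ indels**: sizes are geometric(p = 0.4) truncated at 30 nt, an
  insertion with probability 0.3 and otherwise a deletion. Deletions are
  centred on the cut (start = cut − size//2); insertions add uniform random
  bases at the cut. No published indel spectrum is being fit; the estimators
  only require that indels produce alignment gaps inside the window, and a
  small-indel-dominated spectrum is the standard assumption.
* **HDR alleles** are the donor-reconstructed edited allele (by default the
  amplicon with the 12-nt HindIII+NheI cassette inserted at the cut).
* **Qualities**: bases are Q37 ± 2. With probability 0.05 a read gets a
  Q2 tail of 5–30 nt (removed by windowed trimming; the read survives
  shortened) and with probability 0.01 one internal base drops to Q20
  (trim-proof, so the whole-read Q30 filter removes the read). Both filter
  paths are thereby exercised at realistic, small rates. Substitution errors
  are drawn independently of the quality string.
* **Geometry**: R1 is the allele's first 300 nt, R2 the reverse complement
  of its last 300 nt. The default synthetic locus places the protospacer
  100 nt from the 5' end, so R1 covers the window and R2 never can
  (640 > 600): the far-side mates are length-filtered at classification,
  halving informative depth exactly as with real long amplicons read from
  one informative side.

What the simulator does **not** model: PCR chimeras and jackpots, correlated
or position-dependent error profiles, microhomology-mediated deletion
spectra, adapter read-through. Passing recovery tests therefore demonstrates
correctness of the estimators under idealised noise, not robustness to
library artefacts.

All randomness flows from one `numpy` generator seeded from the config; a
fixed seed gives byte-identical FASTQ and truth files.

## Preprocessing

"Merging" of mates is pooling, not overlap assembly: with 300-nt reads on a
640-nt amplicon the mates cannot overlap, so each read is analysed
independently and the pool is R1 survivors followed by reverse-complemented
R2 survivors (deterministic order). Filtering is 3'-windowed adaptive
trimming (window 4, drop trailing bases while the window mean is below Q30)
followed by whole-read removal if any remaining base is below Q30. Removal
after trimming makes the guarantee exact — no surviving base is sub-Q30 —
and makes the filter idempotent. A high-quality body can shield the last
tail base from mean-based trimming; the hard filter then removes the read,
which is the documented interaction of the two rules. Adapter clipping
(exact 3' prefix match, ≥3 nt) is available but off by default since the
simulator emits adapter-free reads.

## Alignment

Local alignment uses the Gotoh three-state affine formulation (M/D/I
matrices, all floored at 0). Gap cost follows the EMBOSS convention,
`open + extend·L` for a gap of length L, with defaults +5/−4 match/mismatch
and 10/0.5 open/extend — the classic defaults of the water-style aligners
this workflow is built around; all four are configurable. Both gap states
accept transitions from the opposite gap state (charged as a new open), so
the DP optimum equals the optimum over all operation strings, which is what
the brute-force oracle in the tests enumerates.

Determinism: the traceback prefers diagonal over deletion (gap in read)
over insertion (gap in reference), and among equal-scoring end cells the
smallest (ref_end, read_end) wins. Alignments end in an aligned pair (a
trailing gap never raises a local score). Indel placement in homopolymers is
tie-dependent under any such rule; classification only uses gap presence and
inserted bases, so calls are unaffected. Each read is aligned in both
orientations and the higher-scoring one kept (forward on ties) — a
generalisation that makes the pipeline robust to un-normalised read
orientation. The O(m·n) fill/traceback kernels are plain loops JIT-compiled
with numba; without numba the same code runs unmodified, slowly.

## Classification and summaries

A read is informative only when its alignment covers the full window
("at least window-length" alignment is read as full reference coverage:
against a 53-nt reference, nothing shorter can reach 53 columns, and
partial coverage is indistinguishable from a terminal deletion). Gapless
informative reads are non-indel — substitution-only differences never count
as editing, so sequencing errors cannot inflate TE. Gapped reads are HDR if
the expected insert occurs exactly (first inside inserted bases, else as a
substring of the oriented read, covering aligners that split the insertion);
otherwise NHEJ. Insert matching is exact by design — the diagnostic key is
a fixed restriction cassette — and mismatch-tolerant matching is out of
scope. HDR reads count as indel reads in TE, since the insertion produces a
gap. Filtered reads are excluded from every denominator; HDR/TE is reported
as missing when no indel read exists.

## Gel estimators

With band intensities a (substrate) and b, c (products),
f = (b+c)/(a+b+c): T7E1 total editing is (1 − √(1−f))·100 and RFLP HDR is
f·100. Both are scale-invariant in the intensities. The square root undoes
random strand pairing: if edited fraction is m and strands re-anneal at
random, a duplex escapes cleavage only when both strands are wild-type, so
f = 1 − (1−m)². This assumes distinct edited alleles are mutually
mismatched (true for a heterogeneous NHEJ population); the Monte-Carlo
re-annealing simulator also offers a clonal mode (identical mutants re-form
perfect duplexes, f = 2m(1−m)) to show the size of that assumption.
Incomplete enzymatic digestion is not corrected for; band intensities are
numeric inputs and image densitometry is out of scope.

## Pipeline and numerical choices

The orchestrator runs each sample against each locus in a single process,
streaming per read; results are independent of read order by construction.
Summary percentages are written at fixed 4-decimal precision so identical
config+seed reruns produce byte-identical summary files (timestamps appear
only in the log/report metadata, never in `summary.json`). Errors abort the
run with the failing stage and sample named.

## Problem sizes and tolerances used in tests

Recovery tests use 20,000 read pairs (≈19,700 informative reads after
filtering), where binomial noise on a 20–35% fraction is about 0.3 pp at
1σ, against ±1 pp assertions; desk-scale unit tests use 1,500–2,000 pairs
with proportionally wider (3σ) bounds. The aligner is checked against an
independently written affine DP on 500 random pairs up to 30 nt (the oracle
itself validated by exhaustive alignment enumeration below 6 nt), and the
T7E1 inversion uses 10⁵ duplexes per point for ±0.5 pp recovery across
m = 0.1–0.9.

## Known limitations

* Large structural outcomes (deletions past the window, translocations,
  concatemerised donor integration) are invisible to a 53-nt window.
* The HDR call keys on one exact insert string; donor conversions that
  truncate or mutate the cassette are counted as NHEJ.
* TE from gapless-vs-gapped classification misses pure substitution edits
  (by design, to keep sequencing error out of the estimate).
* The T7E1 formula is exact only under the random-pairing,
  mutants-mutually-mismatched assumptions; enzyme kinetics and partial
  digestion are unmodelled.
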