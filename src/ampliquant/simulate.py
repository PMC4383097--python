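"""Synthetic paired-end amplicon reads with known per-read truth.

The generator emulates the statistical structure the quantitation assumes:
a pool of amplicon alleles that are wild-type, NHEJ-edited (an indel centred
at the Cas9 cut site) or HDR-edited (the donor-templated allele carrying the
diagnostic insert), sequenced as non-overlapping paired-end reads (R1 = 5'
end of the allele, R2 = reverse complement of the 3' end) with independent
per-base substitution errors and a simple two-regime quality model.  Every
emitted read carries a truth record so downstream estimates can be scored
against ground truth.

Defaults model the study geometry being emulated: 300-nt reads from a
~640-nt amplicon, NHEJ indel sizes geometric(p=0.4) truncated at 30 nt with
insertions at probability 0.3, and mostly-Q37 bases with a configurable
low-quality 3' tail so the Q30 filter is exercised.  All randomness flows
from a single seeded generator; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus import HdrTemplate, TargetLocus, apply_edit, locate_cut_site, revcomp, validate_hdr_template

BASES = "ACGT"

WT, NHEJ, HDR = "WT", "NHEJ", "HDR"

# Diagnostic HDR key: HindIII (AAGCTT) + NheI (GCTAGC) sites.
DEFAULT_HDR_INSERT = "AAGCTTGCTAGC"


@dataclass(frozen=True)
class IndelSizeDistribution:
    """Truncated geometric indel-size model (sizes >= 1)."""

    p: float = 0.4
    max_size: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("geometric p must be in (0, 1]")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")

    def draw(self, rng: np.random.Generator) -> int:
        while True:
            size = int(rng.geometric(self.p))
            if size <= self.max_size:
                return size


@dataclass(frozen=True)
class QualityModel:
    """High-quality bases with occasional low-quality 3' tails and dips.

    Base qualities are ``high_q`` with +/-2 jitter.  With probability
    ``low_tail_fraction`` a read's final 5-30 bases are set to ``low_q``
    (well below the Q30 threshold, so windowed trimming removes them and
    the read survives shortened); with probability ``internal_dip_fraction``
    one internal base drops to ``dip_q`` (sub-Q30 but trim-proof, so the
    whole-read filter removes the read).
    """

    high_q: int = 37
    low_tail_fraction: float = 0.05
    low_q: int = 2
    internal_dip_fraction: float = 0.01
    dip_q: int = 20

    def __post_init__(self) -> None:
        for name in ("low_tail_fraction", "internal_dip_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def draw(self, length: int, rng: np.random.Generator) -> np.ndarray:
        quals = self.high_q + rng.integers(-2, 3, size=length)
        if length and rng.random() < self.low_tail_fraction:
            tail = int(rng.integers(5, 31))
            quals[-min(tail, length):] = self.low_q
        if length and rng.random() < self.internal_dip_fraction:
            quals[int(rng.integers(0, length))] = self.dip_q
        return quals


@dataclass(frozen=True)
class SimulationConfig:
    locus: TargetLocus
    n_read_pairs: int = 1000
    read_length: int = 300
    frac_hdr: float = 0.2
    frac_nhej: float = 0.15
    indel_size_distribution: IndelSizeDistribution = field(default_factory=IndelSizeDistribution)
    insertion_vs_deletion_prob: float = 0.3
    substitution_error_rate: float = 0.001
    quality_model: QualityModel = field(default_factory=QualityModel)
    hdr_insert: str = DEFAULT_HDR_INSERT  # amplicon plus-strand frame
    hdr_template: HdrTemplate | None = None  # overrides hdr_insert if given
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_hdr", "frac_nhej", "insertion_vs_deletion_prob",
                     "substitution_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_hdr + self.frac_nhej > 1:
            raise ValueError("frac_hdr + frac_nhej must be <= 1")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def hdr_allele(self) -> str:
        """The donor-templated allele, from the template when one is given."""
        if self.hdr_template is not None:
            return validate_hdr_template(self.hdr_template, self.locus).edited_allele
        return apply_edit(self.locus.amplicon, locate_cut_site(self.locus), self.hdr_insert)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    allele_class: str  # WT | NHEJ | HDR
    indel_pos: int  # amplicon cut-region coordinate; -1 for WT
    indel_len: int  # inserted (+) or deleted (-) length; 0 for WT
    indel_bases: str  # inserted bases, if any
    n_errors: int  # substitution sequencing errors applied


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_alleles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], list[tuple[str, int, int, str]]]:
    """Draw one allele per read pair.

    NHEJ deletions remove bases spanning the cut (centred on it); NHEJ
    insertions add random bases at the cut.  Returns the allele sequences
    and per-pair truth tuples (class, indel_pos, indel_len, indel_bases).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    amplicon = config.locus.amplicon
    cut = locate_cut_site(config.locus)
    hdr_seq = config.hdr_allele() if config.frac_hdr > 0 else amplicon
    hdr_len = len(hdr_seq) - len(amplicon)

    classes = rng.choice(
        [WT, NHEJ, HDR],
        size=config.n_read_pairs,
        p=[1 - config.frac_nhej - config.frac_hdr, config.frac_nhej, config.frac_hdr],
    )
    alleles: list[str] = []
    truth: list[tuple[str, int, int, str]] = []
    for cls in classes:
        if cls == WT:
            alleles.append(amplicon)
            truth.append((WT, -1, 0, ""))
        elif cls == HDR:
            alleles.append(hdr_seq)
            truth.append((HDR, cut, hdr_len, config.hdr_insert))
        else:
            size = config.indel_size_distribution.draw(rng)
            if rng.random() < config.insertion_vs_deletion_prob:
                bases = _random_bases(rng, size)
                alleles.append(amplicon[:cut] + bases + amplicon[cut:])
                truth.append((NHEJ, cut, size, bases))
            else:
                left = size // 2  # deletion spans the cut
                start = max(0, cut - left)
                alleles.append(amplicon[:start] + amplicon[start + size :])
                truth.append((NHEJ, start, -size, ""))
    return alleles, truth


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    out = list(seq)
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4] \
            if out[i] in BASES else "N"
    return "".join(out), int(hits.size)


def emit_fastq_pairs(
    config: SimulationConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate alleles and write R1/R2 FASTQ plus a truth table.

    R1 is the first ``read_length`` nt of the allele; R2 the reverse
    complement of the last ``read_length`` nt (clipped for short alleles).
    Returns the truth table (one row per read) and writes it as TSV when
    ``truth_path`` is given.  Deterministic under ``config.seed``.
    """
    from .preprocess import PHRED_OFFSET  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    alleles, allele_truth = simulate_alleles(config, rng)

    rows = []
    rate = config.substitution_error_rate
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for k, (allele, (cls, pos, ilen, ibases)) in enumerate(zip(alleles, allele_truth)):
            r1 = allele[: config.read_length]
            r2 = revcomp(allele[-config.read_length :])
            for mate, seq, fh in ((1, r1, f1), (2, r2, f2)):
                seq, n_err = _apply_errors(seq, rate, rng)
                quals = config.quality_model.draw(len(seq), rng)
                qstr = "".join(chr(int(q) + PHRED_OFFSET) for q in quals)
                rid = f"sim_{k:06d}/{mate}"
                fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
                rows.append(TruthRecord(rid, cls, pos, ilen, ibases, n_err))

    table = pd.DataFrame([r.__dict__ for r in rows])
    if truth_path is not None:
        table.to_csv(truth_path, sep="\t", index=False)
    return table


def make_example_locus(seed: int = 20150126, amplicon_length: int = 640,
                       target_offset: int = 100) -> TargetLocus:
    """A deterministic synthetic locus for simulations and examples.

    The protospacer starts ``target_offset`` nt into a random
    ``amplicon_length``-nt amplicon, so a 300-nt R1 fully covers the
    classification window while R2 (from the far end) does not — the
    single-informative-side geometry of long amplicons.
    """
    rng = np.random.default_rng(seed)
    while True:
        amplicon = _random_bases(rng, amplicon_length)
        protospacer = amplicon[target_offset : target_offset + 20]
        pam = amplicon[target_offset + 20 : target_offset + 23]
        pam = pam[0] + "GG"
        amplicon = (
            amplicon[: target_offset + 20] + pam + amplicon[target_offset + 23 :]
        )
        if amplicon.count(protospacer + pam) == 1:
            return TargetLocus(
                name="synthetic_example",
                protospacer=protospacer,
                pam=pam,
                amplicon=amplicon,
                strand="+",
            )
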