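"""Quality filtering and strand-normalised pooling of paired-end reads.

The read-level filter mirrors trim-then-filter behaviour: optional 3'
adapter clipping, 3' windowed adaptive quality trimming (trailing bases are
dropped while the sliding-window mean quality is below the threshold), then
whole-read removal if any remaining base is below the threshold.  Surviving
R1 reads and reverse-complemented surviving R2 reads are pooled into a
single set in R1 orientation; with 300-nt reads on a ~640-nt amplicon the
mates cannot overlap, so each read is analysed independently and no
overlap-merging is attempted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .locus import revcomp

PHRED_OFFSET = 33


class MalformedReadError(ValueError):
    """Sequence and quality lengths disagree, or qualities out of range."""


@dataclass(frozen=True)
class SequencingRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: str = "R1"  # R1 | R2 | pool

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise MalformedReadError(
                f"{self.id}: {len(self.sequence)} bases vs {len(self.qualities)} qualities"
            )
        if any(q < 0 or q > 93 for q in self.qualities):
            raise MalformedReadError(f"{self.id}: PHRED quality outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequencingRead":
        return replace(
            self, sequence=revcomp(self.sequence), qualities=self.qualities[::-1]
        )


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass; totals must reconcile."""

    n_input: int = 0
    n_trimmed: int = 0  # reads that lost >= 1 base (and survived or not)
    n_removed: int = 0  # dropped entirely (sub-threshold base or empty)
    n_survived: int = 0

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        assert self.n_survived + self.n_removed == self.n_input


def _trim_adapter(seq: str, quals: tuple[int, ...], adapter: str, min_overlap: int = 3):
    """Clip an exact adapter-prefix match at the 3' end (>= min_overlap nt)."""
    for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        idx = seq.rfind(adapter[:k])
        if idx >= 0 and idx + k == len(seq):
            return seq[:idx], quals[:idx]
    return seq, quals


def _trim_quality(quals: tuple[int, ...], q_threshold: int, window: int) -> int:
    """Return the kept length after 3' windowed adaptive trimming."""
    end = len(quals)
    while end > 0:
        lo = max(0, end - window)
        win = quals[lo:end]
        if sum(win) / len(win) >= q_threshold:
            break
        end -= 1
    return end


def quality_trim_and_filter(
    reads: Iterable[SequencingRead],
    q_threshold: int = 30,
    window: int = 4,
    adapter: str = "",
) -> tuple[list[SequencingRead], FilterReport]:
    """Trim 3' ends by sliding-window mean quality, then drop any read that
    still contains a base below ``q_threshold``.

    Returns surviving reads (order preserved) and a :class:`FilterReport`.
    The result is idempotent and guarantees no surviving base is below the
    threshold.
    """
    survivors: list[SequencingRead] = []
    report = FilterReport()
    for read in reads:
        report.n_input += 1
        seq, quals = read.sequence, read.qualities
        if adapter:
            seq, quals = _trim_adapter(seq, quals, adapter)
        end = _trim_quality(quals, q_threshold, window)
        if end < len(read):
            report.n_trimmed += 1
        seq, quals = seq[:end], quals[:end]
        if end == 0 or min(quals) < q_threshold:
            report.n_removed += 1
            continue
        report.n_survived += 1
        survivors.append(
            read if end == len(read) else replace(read, sequence=seq, qualities=quals)
        )
    report.check()
    return survivors, report


def pool_pairs(
    r1_reads: Iterable[SequencingRead], r2_reads: Iterable[SequencingRead]
) -> list[SequencingRead]:
    """Pool surviving mates into one read set in R1 orientation.

    R2 reads are reverse-complemented (qualities reversed).  Output order is
    deterministic: the R1 block in input order, then the R2 block.  Unpaired
    survivors are allowed; nothing is deduplicated or dropped.
    """
    pool = [replace(r, mate="pool") for r in r1_reads]
    pool.extend(replace(r.reverse_complement(), mate="pool") for r in r2_reads)
    return pool


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (plain or gzip)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, mate: str = "R1") -> Iterator[SequencingRead]:
    """Parse a 4-line FASTQ (PHRED+33), plain or gzipped."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or not plus.startswith("+"):
                raise MalformedReadError(f"{path}: malformed FASTQ record near {header!r}")
            yield SequencingRead(
                id=header[1:].split()[0],
                sequence=seq.upper(),
                qualities=tuple(ord(c) - PHRED_OFFSET for c in qual),
                mate=mate,
            )


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(reads: Iterable[SequencingRead], path: str | Path) -> None:
    """Write the pooled read set as FASTA (the pipeline's intermediate)."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
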