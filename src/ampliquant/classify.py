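"""Per-read editing calls and per-sample editing frequencies.

A read is informative only if its local alignment covers the full reference
window (partial coverage cannot be distinguished from a terminal deletion).
Informative reads split into:

* ``non_indel`` — gapless alignment; substitution-only differences do not
  count as editing, so sequencing errors cannot inflate the estimate;
* ``indel_hdr`` — the alignment has gaps and the read carries the
  locus-specific diagnostic insert (exact match, checked first inside
  inserted bases, then as a substring of the whole read in case the aligner
  split the insertion across operations);
* ``indel_nhej`` — any other gapped alignment.

Frequencies over informative reads:

    TE%     = 100 * (indel_nhej + indel_hdr) / informative
    HDR%    = 100 * indel_hdr / informative
    HDR/TE% = 100 * HDR% / TE%          (undefined when TE = 0)

HDR events count toward TE because the templated insertion itself produces a
gap: total editing is the sum of all NHEJ and HDR events that give rise to
indels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .align import DELETION, INSERTION, AlignmentResult
from .locus import ReferenceWindow

NON_INDEL, INDEL_NHEJ, INDEL_HDR, FILTERED = (
    "non_indel",
    "indel_nhej",
    "indel_hdr",
    "filtered",
)
CATEGORIES = (NON_INDEL, INDEL_NHEJ, INDEL_HDR, FILTERED)


class NoDataError(ValueError):
    """No informative reads to summarise."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EditCall:
    read_id: str
    category: str
    ref_coverage: int
    gap_count: int
    insert_match: bool


@dataclass(frozen=True)
class EditingSummary:
    n_non_indel: int
    n_indel_nhej: int
    n_indel_hdr: int
    n_filtered: int

    @property
    def n_informative(self) -> int:
        return self.n_non_indel + self.n_indel_nhej + self.n_indel_hdr

    @property
    def n_indel(self) -> int:
        return self.n_indel_nhej + self.n_indel_hdr

    @property
    def te_pct(self) -> float:
        return 100.0 * self.n_indel / self.n_informative

    @property
    def hdr_pct(self) -> float:
        return 100.0 * self.n_indel_hdr / self.n_informative

    @property
    def hdr_over_te_pct(self) -> float | None:
        if self.n_indel == 0:
            return None
        return 100.0 * self.hdr_pct / self.te_pct

    def as_dict(self) -> dict:
        return {
            "n_non_indel": self.n_non_indel,
            "n_indel_nhej": self.n_indel_nhej,
            "n_indel_hdr": self.n_indel_hdr,
            "n_filtered": self.n_filtered,
            "n_informative": self.n_informative,
            "te_pct": round(self.te_pct, 4),
            "hdr_pct": round(self.hdr_pct, 4),
            "hdr_over_te_pct": (
                None if self.hdr_over_te_pct is None else round(self.hdr_over_te_pct, 4)
            ),
        }


def classify_read(
    aln: AlignmentResult,
    window: ReferenceWindow,
    read_id: str = "",
    call_hdr: bool = True,
) -> EditCall:
    """Categorise one aligned read.

    ``call_hdr=False`` disables HDR detection (all gapped reads become
    ``indel_nhej``); with it enabled the window must define the expected
    insert.
    """
    if call_hdr and not window.expected_insert:
        raise ConfigurationError(
            "HDR calling requested but the reference window has no expected_insert"
        )
    coverage = aln.ref_end - aln.ref_start
    gaps = sum(1 for op in aln.operations if op.op in (INSERTION, DELETION))
    if coverage < len(window):
        return EditCall(read_id, FILTERED, coverage, gaps, False)
    if gaps == 0:
        return EditCall(read_id, NON_INDEL, coverage, 0, False)
    if call_hdr:
        key = window.expected_insert
        hit = any(
            op.op == INSERTION and key in op.bases for op in aln.operations
        ) or key in aln.read
        if hit:
            return EditCall(read_id, INDEL_HDR, coverage, gaps, True)
    return EditCall(read_id, INDEL_NHEJ, coverage, gaps, False)


def summarize_editing(calls: Iterable[EditCall]) -> EditingSummary:
    """Aggregate per-read calls into the three editing frequencies.

    Filtered reads are excluded from every denominator; raises
    :class:`NoDataError` if no informative read remains.  The summary is
    invariant to read order.
    """
    counts = Counter(call.category for call in calls)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    summary = EditingSummary(
        n_non_indel=counts[NON_INDEL],
        n_indel_nhej=counts[INDEL_NHEJ],
        n_indel_hdr=counts[INDEL_HDR],
        n_filtered=counts[FILTERED],
    )
    if summary.n_informative == 0:
        raise NoDataError("no informative reads (all filtered or empty input)")
    return summary
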