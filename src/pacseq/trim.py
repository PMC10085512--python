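"""Adapter trimming and read cleanup.

Single-end sRNA libraries read through the insert into the 3' adapter, so
detecting the adapter both delimits the insert and certifies that the full
small RNA was sequenced.  The default policy therefore *discards* reads in
which no adapter is found.

The adapter search is leftmost-position prefix-overlap matching: the insert
ends at the first position ``p`` where ``read[p:]`` matches a prefix of the
adapter with at least ``min_overlap`` bases compared (or the whole adapter,
if it fits) and at most ``floor(max_mismatch_fraction * overlap)``
mismatches.  No indels are considered, consistent with a substitution-only
error model.  Leftmost wins: against adapter read-through the shortest
insert is the conservative call.

After adapter removal the insert passes, in order, a size window (default
16-75 nt), an ambiguous-base cap, and an optional mean-quality threshold;
each read ends up retained or in exactly one discard category, so the
per-sample report partitions the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import NamedTuple

from pacseq._fastq import read_fastq


@dataclass(frozen=True)
class TrimParams:
    """Adapter definition and read-cleanup tolerances."""

    adapter: str
    max_mismatch_fraction: float = 0.1
    min_overlap: int = 10
    size_range: tuple[int, int] = (16, 75)
    policy_no_adapter: str = "discard"
    max_N: int = 0
    min_mean_quality: float | None = None

    def __post_init__(self):
        if not self.adapter or set(self.adapter.upper()) - set("ACGT"):
            raise ValueError("adapter must be a non-empty ACGT string")
        object.__setattr__(self, "adapter", self.adapter.upper())
        if not 0.0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError("max_mismatch_fraction must be in [0, 0.5)")
        if not 1 <= self.min_overlap <= len(self.adapter):
            raise ValueError("min_overlap must be in [1, adapter length]")
        lo, hi = self.size_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid size_range {self.size_range}")
        if self.policy_no_adapter not in ("discard", "keep"):
            raise ValueError("policy_no_adapter must be 'discard' or 'keep'")
        if self.max_N < 0:
            raise ValueError("max_N must be >= 0")


@dataclass
class TrimReport:
    """Per-sample read accounting; categories partition ``reads_in``."""

    sample: str = ""
    reads_in: int = 0
    reads_with_adapter: int = 0
    reads_discarded_no_adapter: int = 0
    reads_discarded_size: int = 0
    reads_discarded_N: int = 0
    reads_discarded_quality: int = 0
    reads_retained: int = 0

    def check_conservation(self) -> bool:
        return self.reads_in == (
            self.reads_retained
            + self.reads_discarded_no_adapter
            + self.reads_discarded_size
            + self.reads_discarded_N
            + self.reads_discarded_quality
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class TrimOutcome(NamedTuple):
    insert: str | None
    reason: str | None  # None when retained; else no_adapter|size|N|quality


def find_adapter(read: str, params: TrimParams) -> int | None:
    """Leftmost 0-based index at which the 3' adapter starts, or None.

    Position 0 (empty insert) is a legal match.  The number of compared
    bases at position ``p`` is ``min(len(read) - p, len(adapter))`` and must
    reach ``min_overlap``; allowed mismatches scale with the overlap.
    """
    read = read.upper()
    adapter = params.adapter
    n, m = len(read), len(adapter)
    last_p = n - params.min_overlap
    for p in range(0, last_p + 1):
        overlap = min(n - p, m)
        budget = int(params.max_mismatch_fraction * overlap)
        mm = 0
        for i in range(overlap):
            if read[p + i] != adapter[i]:
                mm += 1
                if mm > budget:
                    break
        else:
            return p
    return None


def trim_read(read: str, quality: str, params: TrimParams) -> TrimOutcome:
    """Trim one read; returns the retained insert or a single discard reason."""
    if len(read) != len(quality):
        raise ValueError(
            f"read and quality lengths differ ({len(read)} vs {len(quality)})"
        )
    read = read.upper()
    p = find_adapter(read, params)
    if p is None:
        if params.policy_no_adapter == "discard":
            return TrimOutcome(None, "no_adapter")
        insert, qual = read, quality
    else:
        insert, qual = read[:p], quality[:p]
    lo, hi = params.size_range
    if not lo <= len(insert) <= hi:
        return TrimOutcome(None, "size")
    if sum(1 for b in insert if b not in "ACGT") > params.max_N:
        return TrimOutcome(None, "N")
    if params.min_mean_quality is not None:
        mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
        if mean_q < params.min_mean_quality:
            return TrimOutcome(None, "quality")
    return TrimOutcome(insert, None)


def trim_fastq(path: str | Path, params: TrimParams,
               sample: str | None = None) -> tuple[Counter, TrimReport]:
    """Trim every record of a FASTQ file (plain or gzip).

    Returns the multiset of retained insert sequences and the accounting
    report.  Inserts containing N are excluded from PAC keys by the default
    ``max_N=0``, so downstream sequence keys are pure ACGT.
    """
    path = Path(path)
    report = TrimReport(sample=sample or path.name.split(".")[0])
    inserts: Counter = Counter()
    for rec in read_fastq(path):
        report.reads_in += 1
        p = find_adapter(rec.sequence, params)
        if p is not None:
            report.reads_with_adapter += 1
        outcome = trim_read(rec.sequence, rec.quality, params)
        if outcome.insert is not None:
            inserts[outcome.insert] += 1
            report.reads_retained += 1
        else:
            setattr(report, f"reads_discarded_{outcome.reason}",
                    getattr(report, f"reads_discarded_{outcome.reason}") + 1)
    assert report.check_conservation()
    return inserts, report
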