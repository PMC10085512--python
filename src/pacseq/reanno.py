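"""Hierarchical multi-reference annotation of unique sequences.

Each unique sequence of a count table is aligned, end-to-end and ungapped,
against an ordered collection of reference sets (miRNA hairpins, tRNA,
rRNA, microbial genomes, ...) allowing up to k mismatches (k <= 3).  For
every reference set the *mismatch stratum* — the minimum Hamming distance
at which the sequence hits anywhere in the set — is recorded, together with
the number of hits at that stratum.  Because counting happened before any
alignment, reannotation can be repeated at any time with different
references or mismatch allowances without touching the counts.

Multimapping is never resolved to a single locus: all hits are kept, and
classes are resolved only at the level of a user-declared hierarchy (e.g.
rRNA before miRNA before tRNA), replacing silent multimap arbitration.

The aligner reports ALL placements on both strands with Hamming distance
<= k.  It is an exact vectorized sliding-window scan — every window of the
reference is compared against the query, so the hit set is identical to a
brute-force enumeration by construction.  Minus-strand hits are found by
scanning the reverse complement of the query and are reported at forward-
strand coordinates (0-based, half-open).  Raising k can only add hits
(hits(k) is a subset of hits(k+1)) — which is exactly why permissive
mismatch settings inflate false-positive alignments of random sequences;
:func:`false_positive_curve` measures that inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STRATA = ("mis0", "mis1", "mis2", "mis3")
NO_HIT = "no_hit"
NO_ANNO = "no_anno"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"{what} must be non-empty ACGT (ambiguity codes rejected)")
    return seq


@dataclass(frozen=True)
class ReferenceSet:
    """A named FASTA-like set of reference sequences (ids -> ACGT strings)."""

    name: str
    records: dict[str, str]

    def __post_init__(self):
        clean = {}
        for rid, seq in self.records.items():
            clean[rid] = _check_dna(seq, f"reference {self.name}/{rid}")
        object.__setattr__(self, "records", clean)

    @classmethod
    def from_fasta(cls, name: str, path: str | Path) -> "ReferenceSet":
        from Bio import SeqIO

        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate record id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
        if not records:
            raise ValueError(f"no records in {path}")
        return cls(name=name, records=records)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


@dataclass(frozen=True)
class AlignSpec:
    """Mismatch allowance and strand handling for the internal aligner."""

    max_mismatch: int = 0
    strands: str = "both"

    def __post_init__(self):
        if not 0 <= self.max_mismatch <= 3:
            raise ValueError("max_mismatch must be in 0..3")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")


class HitRecord(NamedTuple):
    query: str
    ref_set: str
    record_id: str
    position: int  # 0-based start on the reference forward strand
    strand: str  # "+" or "-"
    mismatches: int


def _window_mismatches(ref_arr: np.ndarray, q_arr: np.ndarray) -> np.ndarray:
    """Hamming distance of the query against every window of the reference."""
    m = q_arr.size
    n_windows = ref_arr.size - m + 1
    mism = np.zeros(n_windows, dtype=np.int32)
    for i in range(m):
        mism += ref_arr[i : i + n_windows] != q_arr[i]
    return mism


def align_k_mismatch(query: str, ref: ReferenceSet, spec: AlignSpec) -> list[HitRecord]:
    """All end-to-end placements of the query with <= k mismatches.

    Hits are returned in deterministic order (record id, position, strand).
    """
    query = _check_dna(query, "query")
    strands = [("+", query)]
    if spec.strands == "both":
        strands.append(("-", revcomp(query)))
    hits: list[HitRecord] = []
    for rid in sorted(ref.records):
        rseq = ref.records[rid]
        if len(query) > len(rseq):
            continue
        ref_arr = _encode(rseq)
        for strand, q in strands:
            mism = _window_mismatches(ref_arr, _encode(q))
            for pos in np.flatnonzero(mism <= spec.max_mismatch):
                hits.append(HitRecord(query, ref.name, rid, int(pos), strand,
                                      int(mism[pos])))
    hits.sort(key=lambda h: (h.record_id, h.position, h.strand))
    return hits


def _min_mismatch(query: str, ref: ReferenceSet, spec: AlignSpec) -> tuple[int | None, int]:
    """(minimum mismatch <= k or None, number of hits at that minimum)."""
    query = query.upper()
    strands = [query]
    if spec.strands == "both":
        strands.append(revcomp(query))
    best: int | None = None
    n_best = 0
    for rseq in ref.records.values():
        if len(query) > len(rseq):
            continue
        ref_arr = _encode(rseq)
        for q in strands:
            mism = _window_mismatches(ref_arr, _encode(q))
            lo = int(mism.min())
            if lo > spec.max_mismatch:
                continue
            if best is None or lo < best:
                best, n_best = lo, int((mism == lo).sum())
            elif lo == best:
                n_best += int((mism == lo).sum())
    return best, n_best


def reanno(sequences: Sequence[str], refs: Sequence[ReferenceSet],
           spec: AlignSpec | None = None) -> pd.DataFrame:
    """Per-sequence, per-reference mismatch strata.

    Returns a table indexed by sequence with, for each reference set,
    ``<set>_stratum`` in {mis0..mis3, no_hit} and ``<set>_nhits`` — the hit
    count at that minimal stratum.
    """
    spec = spec or AlignSpec()
    if not refs:
        raise ValueError("need at least one reference set")
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ValueError("reference set names must be unique")
    cols: dict[str, list] = {}
    for ref in refs:
        strata, nhits = [], []
        for seq in sequences:
            best, n = _min_mismatch(seq, ref, spec)
            strata.append(NO_HIT if best is None else STRATA[best])
            nhits.append(n)
        cols[f"{ref.name}_stratum"] = strata
        cols[f"{ref.name}_nhits"] = nhits
    table = pd.DataFrame(cols, index=pd.Index(list(sequences), name="seq"))
    return table


@dataclass(frozen=True)
class HierarchySpec:
    """Ordered class priority: list of (class label, reference set name(s)).

    The first class in the order that has any hit wins under the default
    strict policy.  Sequences hitting nothing get the fallback label.
    """

    levels: Sequence[tuple[str, Sequence[str] | str]]
    fallback: str = NO_ANNO

    def normalized(self) -> list[tuple[str, list[str]]]:
        out = []
        for label, sets in self.levels:
            out.append((label, [sets] if isinstance(sets, str) else list(sets)))
        return out


def simplify_reanno(table: pd.DataFrame, hierarchy: HierarchySpec,
                    mismatch_policy: str = "strict_hierarchy") -> pd.DataFrame:
    """Resolve one class per sequence from its per-reference strata.

    ``strict_hierarchy`` (default): the first class in hierarchy order with
    any hit wins, annotated with its minimal stratum.
    ``prefer_less_mismatch_within_class``: the class with the smallest
    stratum wins; hierarchy order breaks ties.  Unresolved sequences get the
    fallback label.  Returns a copy of the table with ``resolved_class``
    and ``resolved_stratum`` columns appended.
    """
    if mismatch_policy not in ("strict_hierarchy", "prefer_less_mismatch_within_class"):
        raise ValueError(f"unknown mismatch_policy {mismatch_policy!r}")
    levels = hierarchy.normalized()
    for label, sets in levels:
        for s in sets:
            if f"{s}_stratum" not in table.columns:
                raise ValueError(f"hierarchy names unknown reference set {s!r}")

    stratum_rank = {s: i for i, s in enumerate(STRATA)}

    def class_stratum(row, sets: list[str]) -> int | None:
        vals = [stratum_rank[row[f"{s}_stratum"]] for s in sets
                if row[f"{s}_stratum"] != NO_HIT]
        return min(vals) if vals else None

    resolved, resolved_stratum = [], []
    for _, row in table.iterrows():
        per_class = [(label, class_stratum(row, sets)) for label, sets in levels]
        hitting = [(label, st) for label, st in per_class if st is not None]
        if not hitting:
            resolved.append(hierarchy.fallback)
            resolved_stratum.append(NO_HIT)
            continue
        if mismatch_policy == "strict_hierarchy":
            label, st = hitting[0]
        else:
            best = min(st for _, st in hitting)
            label, st = next((l, s) for l, s in hitting if s == best)
        resolved.append(label)
        resolved_stratum.append(STRATA[st])
    out = table.copy()
    out["resolved_class"] = resolved
    out["resolved_stratum"] = resolved_stratum
    return out


def false_positive_curve(lengths: Sequence[int], ref: ReferenceSet,
                         k_values: Sequence[int], n: int, seed: int,
                         return_queries: bool = False):
    """Fraction of random sequences hitting the reference, per mismatch allowance.

    Draws ``n`` uniform-random sequences whose lengths are sampled from the
    given empirical length distribution, then reports for each k the
    fraction with at least one <= k-mismatch hit, plus the ratio to the
    perfect-mapping (k=0) fraction.  Non-decreasing in k by the hit-set
    superset property; the inflation of this curve is the false-positive
    cost of permissive mismatch settings.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length distribution")
    k_values = sorted(set(int(k) for k in k_values))
    k_max = max(k_values)
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref_arrs = [_encode(s) for s in ref.records.values()]
    min_dists = np.full(n, k_max + 1, dtype=np.int32)
    queries: list[str] = []
    for i in range(n):
        L = int(lengths[int(rng.integers(len(lengths)))])
        q = rng.choice(bases, size=L)
        queries.append(q.tobytes().decode("ascii"))
        qr = _encode(revcomp(q.tobytes().decode("ascii")))
        best = k_max + 1
        for ref_arr in ref_arrs:
            if L > ref_arr.size:
                continue
            for qq in (q, qr):
                d = int(_window_mismatches(ref_arr, qq).min())
                if d < best:
                    best = d
                    if best == 0:
                        break
            if best == 0:
                break
        min_dists[i] = best
    rows = []
    frac0 = float((min_dists <= 0).mean()) if 0 in k_values else None
    for k in k_values:
        frac = float((min_dists <= k).mean())
        ratio = (frac / frac0) if frac0 else np.nan
        rows.append({"k": k, "fraction_hit": frac, "ratio_to_k0": ratio})
    table = pd.DataFrame(rows)
    if return_queries:
        return table, queries
    return table
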