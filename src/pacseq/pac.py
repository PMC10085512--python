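"""The PAC object: Pheno, Anno and Counts tables keyed by exact sequences.

A PAC object is the package's central container.  Counts is an integer
matrix of unique read sequences (rows) by samples (columns); Anno carries
one row per sequence (sequence length plus any annotation columns appended
later by reannotation or tRF classification); Pheno carries one row of
metadata per sample.  The three tables are kept key- and order-aligned:
``counts.index == anno.index`` and ``counts.columns == pheno.index``,
element for element.  Because the row key IS the read sequence, any number
in any downstream result can be traced to the literal reads of the raw
FASTQ files.

Row order is deterministic (total count descending, ties lexicographic) so
that written outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEQ_KEY = "seq"


class PACError(ValueError):
    pass


class EmptyPACError(PACError):
    """A filter removed every row or every column."""


@dataclass(frozen=True)
class EvidenceFilter:
    """Minimum evidence for a sequence to enter the count table.

    A sequence is kept iff it reaches ``min_count`` reads in at least
    ``min_samples`` distinct samples.  Defaults (2, 2) are a conservative
    noise filter; (1, 1) keeps every observed sequence.
    """

    min_count: int = 2
    min_samples: int = 2

    def __post_init__(self):
        if self.min_count < 1 or self.min_samples < 1:
            raise ValueError("min_count and min_samples must be >= 1")


@dataclass
class PACObject:
    """Pheno (samples x metadata), Anno (sequences x annotations), Counts."""

    pheno: pd.DataFrame
    anno: pd.DataFrame
    counts: pd.DataFrame

    def copy(self) -> "PACObject":
        return PACObject(self.pheno.copy(), self.anno.copy(), self.counts.copy())

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.counts.shape[0]

    def __repr__(self) -> str:
        return (f"PACObject({self.n_sequences} sequences x {self.n_samples} samples, "
                f"anno columns: {list(self.anno.columns)})")


def _ordered_index(counts: pd.DataFrame) -> pd.Index:
    totals = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda s: (-totals[s], s))
    return pd.Index(order, name=SEQ_KEY)


def make_counts(per_sample_inserts: Mapping[str, Mapping[str, int]],
                evidence: EvidenceFilter | None = None) -> pd.DataFrame:
    """Tally per-sample insert multisets into a sequence x sample count table.

    Cell (s, j) is the multiplicity of sequence s among sample j's retained
    inserts.  Rows failing the evidence filter are dropped; remaining rows
    are ordered by descending total count, ties lexicographic.
    """
    evidence = evidence or EvidenceFilter()
    samples = list(per_sample_inserts)
    if not samples:
        raise PACError("need at least one sample")
    if len(set(samples)) != len(samples):
        raise PACError("duplicate sample ids")
    counts = pd.DataFrame(
        {s: pd.Series(dict(per_sample_inserts[s]), dtype="int64") for s in samples}
    ).fillna(0).astype("int64")
    counts.index.name = SEQ_KEY
    if counts.empty:
        counts = pd.DataFrame(0, index=pd.Index([], name=SEQ_KEY), columns=samples,
                              dtype="int64")
        return counts
    keep = (counts >= evidence.min_count).sum(axis=1) >= evidence.min_samples
    counts = counts.loc[keep]
    return counts.loc[_ordered_index(counts)]


def make_pac(pheno: pd.DataFrame, counts: pd.DataFrame) -> PACObject:
    """Assemble a PAC object, aligning tables and deriving the Anno table.

    ``pheno`` must be indexed by (or contain a ``sample_id`` column of)
    unique sample ids covering every count column; extra pheno rows are
    dropped.  Anno starts with the sequence-length column.
    """
    pheno = pheno.copy()
    if pheno.index.name != "sample_id" and "sample_id" in pheno.columns:
        pheno = pheno.set_index("sample_id")
    pheno.index = pheno.index.astype(str)
    pheno.index.name = "sample_id"
    if not pheno.index.is_unique:
        raise PACError("pheno sample ids must be unique")
    missing = [c for c in counts.columns if c not in pheno.index]
    if missing:
        raise PACError(f"count columns missing from pheno: {missing}")
    sample_order = [s for s in pheno.index if s in set(counts.columns)]
    pheno = pheno.loc[sample_order]
    counts = counts.loc[:, sample_order].copy()
    counts = counts.loc[_ordered_index(counts)]
    anno = pd.DataFrame({"length": [len(s) for s in counts.index]}, index=counts.index)
    anno.index.name = SEQ_KEY
    return PACObject(pheno=pheno, anno=anno, counts=counts)


def pac_check(pac: PACObject) -> tuple[bool, list[str]]:
    """Verify every structural invariant; returns (ok, violations)."""
    v: list[str] = []
    if not pac.pheno.index.is_unique:
        v.append("duplicate sample ids in pheno")
    if not pac.anno.index.is_unique:
        v.append("duplicate sequence keys in anno")
    if list(pac.counts.index) != list(pac.anno.index):
        v.append("row key mismatch between counts and anno")
    if list(pac.counts.columns) != list(pac.pheno.index):
        v.append("column key mismatch between counts and pheno")
    if len(pac.counts) and (pac.counts.to_numpy() < 0).any():
        v.append("negative counts")
    if "length" in pac.anno.columns:
        lengths = pac.anno["length"]
        if any(lengths.loc[s] != len(s) for s in pac.anno.index):
            v.append("anno length column inconsistent with sequence keys")
    return (not v, v)


def pac_filter(
    pac: PACObject,
    size_range: tuple[int, int] | None = None,
    min_cpm: float | None = None,
    min_samples_over_cpm: int = 1,
    pheno_subset: Callable[[pd.DataFrame], pd.Series] | None = None,
    anno_subset: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> PACObject:
    """Return a new PAC restricted to rows/columns passing all predicates.

    ``min_cpm`` keeps sequences reaching that CPM in at least
    ``min_samples_over_cpm`` of the *remaining* samples (CPM computed on
    the remaining columns' full library sizes).  Predicates receive the
    pheno/anno table and return a boolean mask.  Raises
    :class:`EmptyPACError` if nothing survives.
    """
    out = pac.copy()
    if pheno_subset is not None:
        mask = np.asarray(pheno_subset(out.pheno), dtype=bool)
        out.pheno = out.pheno.loc[mask]
        out.counts = out.counts.loc[:, out.pheno.index]
    if out.counts.shape[1] == 0:
        raise EmptyPACError("sample filter removed all samples")
    row_mask = pd.Series(True, index=out.counts.index)
    if size_range is not None:
        lo, hi = size_range
        row_mask &= out.anno["length"].between(lo, hi)
    if anno_subset is not None:
        row_mask &= pd.Series(np.asarray(anno_subset(out.anno), dtype=bool),
                              index=out.anno.index)
    if min_cpm is not None:
        cpm = pac_norm(out)
        row_mask &= (cpm >= min_cpm).sum(axis=1) >= min_samples_over_cpm
    out.counts = out.counts.loc[row_mask]
    out.anno = out.anno.loc[row_mask]
    if out.counts.shape[0] == 0:
        raise EmptyPACError("sequence filter removed all sequences")
    return out


def pac_norm(pac: PACObject, method: str = "cpm") -> pd.DataFrame:
    """Counts-per-million normalization, aligned with the count table.

    cpm(s, j) = counts(s, j) * 1e6 / library size of sample j, where the
    library size is the column total of the *current* count table (computed
    before any row filtering within this call).
    """
    if method != "cpm":
        raise ValueError(f"unknown normalization method {method!r}")
    totals = pac.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise PACError(f"zero library size for sample(s): {list(zero.index)}")
    return pac.counts * 1e6 / totals


def pac_summary(pac: PACObject, group_column: str, stat: str = "mean_cpm",
                reference_level: str | None = None,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Group-level summaries of normalized counts.

    ``mean_cpm``: arithmetic mean CPM per group.  ``log2fc``: log2 fold
    change of group mean CPMs with a pseudocount (default 1 CPM, avoiding
    infinities on dropouts); needs exactly two groups, or a stated
    ``reference_level`` against which every other group is compared.
    """
    if group_column not in pac.pheno.columns:
        raise PACError(f"unknown pheno column {group_column!r}")
    cpm = pac_norm(pac)
    groups = pac.pheno[group_column]
    means = {g: cpm.loc[:, groups[groups == g].index].mean(axis=1)
             for g in pd.unique(groups)}
    if stat == "mean_cpm":
        return pd.DataFrame(means)
    if stat == "log2fc":
        names = list(means)
        if reference_level is None:
            if len(names) != 2:
                raise PACError("log2fc needs exactly 2 groups or a reference_level")
            a, b = names
            return pd.DataFrame({
                f"{a}_vs_{b}": np.log2((means[a] + pseudocount) / (means[b] + pseudocount))
            })
        if reference_level not in means:
            raise PACError(f"reference level {reference_level!r} not in {names}")
        ref = means[reference_level] + pseudocount
        return pd.DataFrame({
            f"{g}_vs_{reference_level}": np.log2((means[g] + pseudocount) / ref)
            for g in names if g != reference_level
        })
    raise ValueError(f"unknown stat {stat!r}")


def write_pac(pac: PACObject, out_dir: str | Path,
              manifest_extra: Mapping | None = None) -> Path:
    """Write a PAC directory: pheno.tsv, anno.tsv, counts.tsv + manifest.json."""
    from pacseq.pipeline import file_digest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pac.pheno.to_csv(out_dir / "pheno.tsv", sep="\t")
    pac.anno.to_csv(out_dir / "anno.tsv", sep="\t")
    pac.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    from pacseq import __version__

    manifest = {
        "tool": "pacseq",
        "version": __version__,
        "tables": {
            name: file_digest(out_dir / f"{name}.tsv")
            for name in ("pheno", "anno", "counts")
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def read_pac(pac_dir: str | Path) -> PACObject:
    """Read a PAC directory written by :func:`write_pac`."""
    pac_dir = Path(pac_dir)
    pheno = pd.read_csv(pac_dir / "pheno.tsv", sep="\t", index_col="sample_id")
    pheno.index = pheno.index.astype(str)
    anno = pd.read_csv(pac_dir / "anno.tsv", sep="\t", index_col=SEQ_KEY)
    counts = pd.read_csv(pac_dir / "counts.tsv", sep="\t", index_col=SEQ_KEY)
    counts.columns = counts.columns.astype(str)
    return PACObject(pheno=pheno, anno=anno, counts=counts.astype("int64"))
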