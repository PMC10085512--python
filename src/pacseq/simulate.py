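"""Synthetic small-RNA sequencing fixtures with known ground truth.

Every downstream stage (trimming, counting, reannotation, tRF
classification, contamination modelling) is testable against data whose true
composition is known exactly, without downloading any public accession.  A
simulated sample is a mixture over *source pools* (e.g. a host reference and
one or more contaminant references): each read is an insert — a substring of
a pool sequence, with optional substitution errors — followed by as much of
the 3' adapter as fits the fixed read length, padded with random
read-through bases.  A configurable fraction of reads carries no adapter at
all, exercising the default discard policy of the trimmer.

Defaults emulate a typical single-end sRNA library: 75 nt reads (so the 3'
adapter is always sequenced deep enough to be detected behind the longest
insert), inserts drawn uniformly from 16-45 nt (mature sRNA rarely exceeds
75 nt), constant Phred-40 qualities, substitution errors only (no indels).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pacseq._fastq import FastqRecord, write_fastq
from pacseq.trf import TRNAModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Full-length Illumina TruSeq small-RNA 3' adapter prefix used as default.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def gen_references(seed: int, n: int, length: int) -> list[str]:
    """Generate ``n`` i.i.d. uniform-random DNA strings of ``length`` nt.

    Deterministic given ``seed``.  The same generator backs the
    false-positive alignment experiment (random sequences aligned against a
    real or random reference at increasing mismatch allowances).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    block = rng.choice(_BASES, size=(n, length))
    return [row.tobytes().decode("ascii") for row in block]


@dataclass(frozen=True)
class SourcePool:
    """A named set of reference sequences that reads can derive from.

    Parameters
    ----------
    name : str
        Pool label; becomes the ground-truth class of its reads.
    sequences : sequence of str
        Reference sequences over {A,C,G,T}.
    length_dist : sequence of int, optional
        Discrete set of insert lengths sampled uniformly; defaults to
        16..45 nt.  Every length must fit the shortest source sequence.
    """

    name: str
    sequences: Sequence[str]
    length_dist: Sequence[int] = field(default_factory=lambda: tuple(range(16, 46)))

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"pool {self.name!r}: needs at least one sequence")
        for s in self.sequences:
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"pool {self.name!r}: sequences must be non-empty ACGT")
        shortest = min(len(s) for s in self.sequences)
        if not self.length_dist:
            raise ValueError(f"pool {self.name!r}: empty insert length distribution")
        if min(self.length_dist) < 1 or max(self.length_dist) > shortest:
            raise ValueError(
                f"pool {self.name!r}: insert lengths must lie in [1, {shortest}] "
                f"(shortest source sequence)"
            )


@dataclass(frozen=True)
class SimSpec:
    """Full description of a simulated multi-sample sRNA experiment.

    ``per_sample_mixture`` maps sample id -> {pool name -> fraction}; the
    fractions define the expected contamination composition of each library
    and must sum to 1 per sample.  ``adapterless_fraction`` of reads are
    written without any adapter (random bases instead), to exercise the
    trimmer's no-adapter discard rule.
    """

    pools: Sequence[SourcePool]
    per_sample_mixture: Mapping[str, Mapping[str, float]]
    n_reads_per_sample: int = 1000
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    read_length: int = 75
    adapterless_fraction: float = 0.0
    quality: str = "constant"  # "constant" (Phred-40) or "uniform" (Phred 2..40)
    seed: int = 0

    def __post_init__(self):
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError("pool names must be unique")
        if self.n_reads_per_sample < 1:
            raise ValueError("n_reads_per_sample must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if not 0.0 <= self.adapterless_fraction <= 1.0:
            raise ValueError("adapterless_fraction must be in [0, 1]")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be ACGT")
        for sample, mix in self.per_sample_mixture.items():
            fracs = list(mix.values())
            if any(f < 0 or f > 1 for f in fracs):
                raise ValueError(f"sample {sample!r}: mixture fractions must be in [0, 1]")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(f"sample {sample!r}: mixture fractions must sum to 1")
            unknown = set(mix) - set(names)
            if unknown:
                raise ValueError(f"sample {sample!r}: unknown pools {sorted(unknown)}")


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three *other* bases
        idx = np.flatnonzero(hit)
        cur = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_fastq(spec: SimSpec, out_dir: str | Path) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one FASTQ per sample and return (paths, ground-truth table).

    The ground truth has one row per read: read_id, sample, pool, source
    index, insert start/end (0-based half-open on the source sequence) and
    the true insert sequence *before* errors.  Output is byte-identical for
    identical specs (gzip not used; qualities and read-through bases come
    from the seeded generator).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pools = {p.name: p for p in spec.pools}
    rng = np.random.default_rng(spec.seed)
    paths: dict[str, Path] = {}
    truth_rows: list[tuple] = []

    for sample in spec.per_sample_mixture:
        mix = spec.per_sample_mixture[sample]
        pool_names = sorted(mix)
        probs = np.array([mix[p] for p in pool_names], dtype=float)
        probs = probs / probs.sum()
        records: list[FastqRecord] = []
        for i in range(spec.n_reads_per_sample):
            pool = pools[pool_names[rng.choice(len(pool_names), p=probs)]]
            src_idx = int(rng.integers(len(pool.sequences)))
            src = pool.sequences[src_idx]
            ins_len = int(pool.length_dist[int(rng.integers(len(pool.length_dist)))])
            start = int(rng.integers(0, len(src) - ins_len + 1))
            true_insert = src[start : start + ins_len]
            insert = _apply_substitutions(rng, true_insert, spec.error_rate)

            with_adapter = rng.random() >= spec.adapterless_fraction
            tail = spec.adapter if with_adapter else ""
            read = (insert + tail)[: spec.read_length]
            if len(read) < spec.read_length:
                read += _random_dna(rng, spec.read_length - len(read))
            if spec.quality == "constant":
                qual = "I" * len(read)  # Phred 40
            else:
                qual = (np.asarray(rng.integers(2, 41, size=len(read)), dtype=np.uint8) + 33
                        ).tobytes().decode("ascii")
            rid = f"{sample}_read{i}"
            records.append(FastqRecord(rid, read, qual))
            truth_rows.append(
                (rid, sample, pool.name, src_idx, start, start + ins_len, true_insert,
                 with_adapter)
            )
        path = out_dir / f"{sample}.fastq"
        write_fastq(path, records)
        paths[sample] = path

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "pool", "source_id", "insert_start",
                 "insert_end", "insert_seq", "has_adapter"],
    )
    return paths, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def gen_trna_model(
    seed: int,
    acceptor_len: int = 76,
    loop_span: tuple[int, int] = (31, 38),
    cca: bool = True,
    model_id: str | None = None,
) -> TRNAModel:
    """Random tRNA-like reference with recorded anticodon-loop coordinates.

    ``acceptor_len`` is the mature body length (CCA excluded); ``loop_span``
    is the 0-based half-open anticodon-loop interval on the body.  When
    ``cca`` is set the classification reference is body + "CCA".
    """
    start, end = loop_span
    if not (0 <= start < end <= acceptor_len):
        raise ValueError(f"loop span {loop_span} outside body of length {acceptor_len}")
    rng = np.random.default_rng(seed)
    body = _random_dna(rng, acceptor_len)
    return TRNAModel(
        id=model_id or f"tRNA-sim-{seed}",
        body=body,
        loop=(start, end),
        cca=cca,
    )


def spec_from_dict(cfg: Mapping) -> SimSpec:
    """Build a SimSpec from a plain config mapping (YAML/JSON pipeline input)."""
    pools = []
    for p in cfg["pools"]:
        if "sequences" in p:
            seqs = list(p["sequences"])
        else:
            seqs = gen_references(
                int(p.get("seed", 0)), int(p.get("n_sequences", 20)),
                int(p.get("length", 500)),
            )
        kwargs = {}
        if "length_dist" in p:
            kwargs["length_dist"] = tuple(int(x) for x in p["length_dist"])
        elif "insert_range" in p:
            lo, hi = p["insert_range"]
            kwargs["length_dist"] = tuple(range(int(lo), int(hi) + 1))
        pools.append(SourcePool(name=p["name"], sequences=seqs, **kwargs))
    known = {f.name for f in dataclasses.fields(SimSpec)} - {"pools", "per_sample_mixture"}
    extra = {k: v for k, v in cfg.items() if k in known}
    return SimSpec(pools=pools, per_sample_mixture=cfg["per_sample_mixture"], **extra)
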