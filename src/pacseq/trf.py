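"""Positional classification of tRNA-derived fragments (tRFs).

A tRNA-mapped sequence is classified by where its placement starts and ends
on the mature tRNA, using only two coordinates supplied per tRNA: the
anticodon-loop interval and whether the reference carries the
post-transcriptional 3' CCA.  This keeps the classification species-agnostic
— no human-specific lookup table is needed, only a tRNA FASTA plus a loop
coordinate sidecar.

Labels
------
``5p-half`` / ``3p-half``
    terminus-anchored fragments whose internal cleavage point falls inside
    the anticodon loop (the classic angiogenin halves);
``5p-tRF`` / ``3p-tRF``
    terminus-anchored fragments cleaved outside the loop;
``i-tRF``
    internal fragments anchored to neither terminus;
``whole-tRNA``
    both termini anchored.

"Inside the loop" means the fragment's boundary *base* lies within the
half-open loop interval: a 5'-anchored fragment is a half iff its last base
index is in [loop_start, loop_end); a 3'-anchored one iff its first base
index is.  With CCA present, the 3' terminus is the end of body+CCA, so a
fragment stopping at the discriminator base is not 3'-anchored unless the
end tolerance allows it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from pacseq.pac import PACObject

LABELS = ("5p-half", "3p-half", "5p-tRF", "3p-tRF", "i-tRF", "whole-tRNA")
NOT_TRNA = "not_tRNA"


@dataclass(frozen=True)
class TRNAModel:
    """A mature tRNA reference with its anticodon-loop coordinate frame.

    Parameters
    ----------
    id : str
        tRNA identifier (e.g. isoacceptor name).
    body : str
        Mature tRNA sequence *without* the CCA tail.
    loop : (int, int)
        0-based half-open anticodon-loop interval on ``body``.
    cca : bool
        If True, classification runs against ``body + "CCA"``.
    """

    id: str
    body: str
    loop: tuple[int, int]
    cca: bool = True

    def __post_init__(self):
        if not self.body or set(self.body) - set("ACGT"):
            raise ValueError(f"tRNA {self.id!r}: body must be non-empty ACGT")
        start, end = self.loop
        if not (0 <= start < end <= len(self.body)):
            raise ValueError(f"tRNA {self.id!r}: loop {self.loop} outside body")

    @property
    def ref_seq(self) -> str:
        """The sequence fragments are placed on (CCA-inclusive when set)."""
        return self.body + "CCA" if self.cca else self.body

    @property
    def ref_len(self) -> int:
        return len(self.body) + (3 if self.cca else 0)


@dataclass(frozen=True)
class TRFParams:
    """Tolerances and policies for tRF calling.

    end_tolerance : nt of slack when deciding whether a fragment is anchored
        to a terminus (default 0 = exact; 1-2 absorbs non-templated ends).
    max_mismatch : mismatches allowed when placing sequences on tRNAs (0-3).
    multi_trna_policy : "report_all" keeps every placement (no forced unique
        assignment); "majority_label" collapses to the most frequent label.
    """

    end_tolerance: int = 0
    max_mismatch: int = 0
    multi_trna_policy: str = "report_all"

    def __post_init__(self):
        if self.end_tolerance < 0:
            raise ValueError("end_tolerance must be >= 0")
        if not 0 <= self.max_mismatch <= 3:
            raise ValueError("max_mismatch must be in 0..3")
        if self.multi_trna_policy not in ("report_all", "majority_label"):
            raise ValueError(f"unknown multi_trna_policy {self.multi_trna_policy!r}")


def classify_fragment(start: int, end: int, model: TRNAModel,
                      params: TRFParams | None = None) -> str:
    """Label one placement (0-based half-open on the CCA-inclusive reference)."""
    params = params or TRFParams()
    ref_len = model.ref_len
    if not (0 <= start < end <= ref_len):
        raise ValueError(f"interval ({start}, {end}) out of bounds for length {ref_len}")
    tol = params.end_tolerance
    loop_start, loop_end = model.loop
    anchored5 = start <= tol
    anchored3 = end >= ref_len - tol
    if anchored5 and anchored3:
        return "whole-tRNA"
    if anchored5:
        return "5p-half" if loop_start <= end - 1 < loop_end else "5p-tRF"
    if anchored3:
        return "3p-half" if loop_start <= start < loop_end else "3p-tRF"
    return "i-tRF"


def _labels_for_sequence(seq: str, models: list[TRNAModel], params: TRFParams):
    """All minimal-mismatch placements of ``seq`` on the models, with labels."""
    from pacseq.reanno import AlignSpec, ReferenceSet, align_k_mismatch

    spec = AlignSpec(max_mismatch=params.max_mismatch, strands="forward")
    placements = []  # (trna_id, start, end, mismatches, label)
    for model in models:
        ref = ReferenceSet(name=model.id, records={model.id: model.ref_seq})
        for hit in align_k_mismatch(seq, ref, spec):
            end = hit.position + len(seq)
            label = classify_fragment(hit.position, end, model, params)
            placements.append((model.id, hit.position, end, hit.mismatches, label))
    if not placements:
        return []
    best = min(p[3] for p in placements)
    return [p for p in placements if p[3] == best]


def classify_all(pac: "PACObject", models: list[TRNAModel],
                 params: TRFParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sequence of a PAC object against a set of tRNA models.

    Returns ``(calls, summary)``: one call row per minimal-mismatch placement
    (sequence, tRNA, start, end, mismatches, label), and a label x tRNA x
    length tally.  The PAC's Anno table gains a ``trf_label`` column —
    sequences with no placement within ``max_mismatch`` get ``"not_tRNA"``;
    under ``report_all`` a sequence placed with conflicting labels keeps the
    sorted set joined by ``"|"``, under ``majority_label`` the most frequent
    (ties broken alphabetically).
    """
    params = params or TRFParams()
    if not models:
        raise ValueError("need at least one tRNA model")
    call_rows = []
    anno_labels = {}
    for seq in pac.anno.index:
        placements = _labels_for_sequence(seq, models, params)
        if not placements:
            anno_labels[seq] = NOT_TRNA
            continue
        for trna_id, start, end, mm, label in placements:
            call_rows.append((seq, trna_id, start, end, mm, label))
        labels = [p[4] for p in placements]
        if params.multi_trna_policy == "majority_label":
            counts = Counter(labels)
            top = max(counts.values())
            anno_labels[seq] = sorted(l for l, c in counts.items() if c == top)[0]
        else:
            anno_labels[seq] = "|".join(sorted(set(labels)))
    pac.anno["trf_label"] = pd.Series(anno_labels).reindex(pac.anno.index)
    calls = pd.DataFrame(
        call_rows, columns=["seq", "trna", "start", "end", "mismatches", "label"]
    )
    if calls.empty:
        summary = pd.DataFrame(columns=["label", "trna", "length", "n_sequences"])
    else:
        calls["length"] = calls["end"] - calls["start"]
        summary = (
            calls.groupby(["label", "trna", "length"])["seq"]
            .nunique()
            .reset_index(name="n_sequences")
        )
    return calls, summary


def read_trna_models(fasta: str | Path, loops_tsv: str | Path) -> list[TRNAModel]:
    """Load tRNA models from a FASTA plus a TSV sidecar (id, loop_start, loop_end, cca)."""
    from Bio import SeqIO

    coords = pd.read_csv(loops_tsv, sep="\t", dtype={"id": str})
    coords = coords.set_index("id")
    models = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in coords.index:
            raise ValueError(f"tRNA {rec.id!r} missing from loop coordinate table")
        row = coords.loc[rec.id]
        models.append(
            TRNAModel(
                id=rec.id,
                body=str(rec.seq).upper(),
                loop=(int(row["loop_start"]), int(row["loop_end"])),
                cca=bool(row["cca"]) if "cca" in coords.columns else True,
            )
        )
    return models
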