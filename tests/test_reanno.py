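"""Internal aligner and hierarchical annotation: oracle equivalence and
monotonicity of hit sets in the mismatch allowance."""

import numpy as np
import pandas as pd
import pytest

from pacseq import (
    AlignSpec,
    HierarchySpec,
    ReferenceSet,
    SimSpec,
    SourcePool,
    align_k_mismatch,
    false_positive_curve,
    gen_references,
    reanno,
    simplify_reanno,
    simulate_fastq,
)
from pacseq.reanno import revcomp
from tests.conftest import random_dna


def oracle_hits(query, ref, k, strands="both"):
    """Exhaustive sliding-window Hamming scan, independently coded."""
    out = set()
    queries = [("+", query)]
    if strands == "both":
        rc = query[::-1].translate(str.maketrans("ACGT", "TGCA"))
        queries.append(("-", rc))
    for rid, rseq in ref.records.items():
        for strand, q in queries:
            for pos in range(len(rseq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(rseq[pos : pos + len(q)], q))
                if mm <= k:
                    out.add((rid, pos, strand, mm))
    return out


def test_align_exact_positions():
    ref = ReferenceSet("r", {"rec": "ACGTACGT"})
    hits = align_k_mismatch("ACG", ref, AlignSpec(max_mismatch=0, strands="forward"))
    assert [(h.position, h.mismatches) for h in hits] == [(0, 0), (4, 0)]


def test_align_one_mismatch_hit():
    ref = ReferenceSet("r", {"rec": "ACGTACGT"})
    hits = align_k_mismatch("ACGA", ref, AlignSpec(max_mismatch=1, strands="forward"))
    assert any(h.position == 0 and h.mismatches == 1 for h in hits)


def test_align_rejects_ambiguity_codes():
    ref = ReferenceSet("r", {"rec": "ACGTACGT"})
    with pytest.raises(ValueError, match="ambiguity"):
        align_k_mismatch("ACNG", ref, AlignSpec())


def test_align_matches_brute_force_oracle(rng):
    ref = ReferenceSet("r", {"rec": random_dna(rng, 800)})
    for _ in range(80):
        q = random_dna(rng, int(rng.integers(8, 26)))
        for k in range(4):
            got = {(h.record_id, h.position, h.strand, h.mismatches)
                   for h in align_k_mismatch(q, ref, AlignSpec(max_mismatch=k))}
            assert got == oracle_hits(q, ref, k)


def test_hit_set_monotonic_in_k(rng):
    """hits(k) is a subset of hits(k+1): permissive mapping only adds hits."""
    ref = ReferenceSet("r", {"rec": random_dna(rng, 1000)})
    for _ in range(40):
        q = random_dna(rng, 15)
        sets = []
        for k in range(4):
            sets.append({(h.record_id, h.position, h.strand)
                         for h in align_k_mismatch(q, ref, AlignSpec(max_mismatch=k))})
        for a, b in zip(sets, sets[1:]):
            assert a <= b


def test_strand_correctness(rng):
    """Reverse-complementing the reference flips strand labels only."""
    seq = random_dna(rng, 400)
    fwd = ReferenceSet("f", {"rec": seq})
    rev = ReferenceSet("f", {"rec": revcomp(seq)})
    for _ in range(25):
        q = random_dna(rng, 14)
        h_f = {(h.position, h.strand, h.mismatches)
               for h in align_k_mismatch(q, fwd, AlignSpec(max_mismatch=1))}
        h_r = {(len(seq) - (h.position + 14), "+-"[h.strand == "+"], h.mismatches)
               for h in align_k_mismatch(q, rev, AlignSpec(max_mismatch=1))}
        assert h_f == h_r


def test_reanno_strata_and_counts():
    refs = [
        ReferenceSet("miRNA", {"m1": "AAACCCGGGTTTAAACCCGGG"}),
        ReferenceSet("rRNA", {"r1": "TTTTTTTTTTTTTTTTTTTT"}),
    ]
    seqs = ["AAACCCGGG", "TTTTTTTT", "GACGACGAC"]
    table = reanno(seqs, refs, AlignSpec(max_mismatch=0, strands="forward"))
    assert table.loc["AAACCCGGG", "miRNA_stratum"] == "mis0"
    assert table.loc["AAACCCGGG", "miRNA_nhits"] == 2
    assert table.loc["AAACCCGGG", "rRNA_stratum"] == "no_hit"
    assert table.loc["TTTTTTTT", "rRNA_stratum"] == "mis0"
    assert table.loc["TTTTTTTT", "rRNA_nhits"] == 13
    assert table.loc["GACGACGAC", "miRNA_stratum"] == "no_hit"
    assert table.loc["GACGACGAC", "rRNA_stratum"] == "no_hit"


def test_reanno_empty_sequence_list():
    refs = [ReferenceSet("a", {"r": "ACGTACGT"})]
    assert len(reanno([], refs, AlignSpec())) == 0


def oracle_resolve(row, levels, policy, fallback="no_anno"):
    """Independent rule evaluation of the hierarchy policies."""
    rank = {"mis0": 0, "mis1": 1, "mis2": 2, "mis3": 3}
    per_class = []
    for label, sets in levels:
        strata = [rank[row[f"{s}_stratum"]] for s in sets
                  if row[f"{s}_stratum"] != "no_hit"]
        per_class.append((label, min(strata) if strata else None))
    hits = [(l, s) for l, s in per_class if s is not None]
    if not hits:
        return fallback, "no_hit"
    if policy == "strict_hierarchy":
        l, s = hits[0]
    else:
        best = min(s for _, s in hits)
        l, s = [h for h in hits if h[1] == best][0]
    return l, f"mis{s}"


def test_simplify_strict_hierarchy_order_wins():
    table = pd.DataFrame(
        {"rRNA_stratum": ["mis0"], "rRNA_nhits": [1],
         "miRNA_stratum": ["mis0"], "miRNA_nhits": [1]},
        index=pd.Index(["ACGTACGTACGTACGT"], name="seq"))
    hier = HierarchySpec(levels=[("rRNA", "rRNA"), ("miRNA", "miRNA")])
    out = simplify_reanno(table, hier)
    assert out["resolved_class"].iloc[0] == "rRNA"


def test_simplify_no_hits_fallback():
    table = pd.DataFrame(
        {"a_stratum": ["no_hit"], "a_nhits": [0]},
        index=pd.Index(["ACGTACGTACGTACGT"], name="seq"))
    out = simplify_reanno(table, HierarchySpec(levels=[("a", "a")]))
    assert out["resolved_class"].iloc[0] == "no_anno"
    assert out["resolved_stratum"].iloc[0] == "no_hit"


def test_simplify_unknown_set_errors():
    table = pd.DataFrame({"a_stratum": ["mis0"], "a_nhits": [1]},
                         index=pd.Index(["ACGT"], name="seq"))
    with pytest.raises(ValueError, match="unknown reference set"):
        simplify_reanno(table, HierarchySpec(levels=[("b", "b")]))


@pytest.mark.parametrize("policy",
                         ["strict_hierarchy", "prefer_less_mismatch_within_class"])
def test_simplify_matches_rule_oracle(rng, policy):
    strata = ["mis0", "mis1", "mis2", "mis3", "no_hit"]
    sets = ["rRNA", "miRNA", "tRNA"]
    rows = {f"{s}_stratum": [strata[int(rng.integers(5))] for _ in range(200)]
            for s in sets}
    for s in sets:
        rows[f"{s}_nhits"] = [1] * 200
    table = pd.DataFrame(rows, index=pd.Index([f"seq{i}" for i in range(200)],
                                              name="seq"))
    levels = [("rRNA", ["rRNA"]), ("miRNA", ["miRNA"]), ("tRNA", ["tRNA"])]
    out = simplify_reanno(table, HierarchySpec(levels=levels), policy)
    for seq, row in table.iterrows():
        want = oracle_resolve(row, levels, policy)
        assert (out.loc[seq, "resolved_class"], out.loc[seq, "resolved_stratum"]) == want


def test_end_to_end_hierarchy_recovers_pool_labels(adapter, tmp_path):
    """Error-free reads resolve to their true source pool for 100% of sequences."""
    pools = [SourcePool(name, gen_references(seed, 5, 300))
             for name, seed in [("rRNA", 31), ("miRNA", 32), ("microbe", 33)]]
    spec = SimSpec(pools=pools,
                   per_sample_mixture={"s": {"rRNA": 0.3, "miRNA": 0.4, "microbe": 0.3}},
                   n_reads_per_sample=600, adapter=adapter, seed=34)
    _, truth = simulate_fastq(spec, tmp_path)
    refs = [ReferenceSet(p.name, {f"r{i}": s for i, s in enumerate(p.sequences)})
            for p in pools]
    seqs = sorted(set(truth["insert_seq"]))
    table = reanno(seqs, refs, AlignSpec(max_mismatch=0))
    hier = HierarchySpec(levels=[("rRNA", "rRNA"), ("miRNA", "miRNA"),
                                 ("microbe", "microbe")])
    resolved = simplify_reanno(table, hier)["resolved_class"]
    # >=16-mers drawn from independent random pools never collide by chance,
    # so each sequence has exactly one true pool label
    truth_label = truth.groupby("insert_seq")["pool"].agg(set)
    assert all(len(s) == 1 for s in truth_label)
    for seq in seqs:
        assert resolved[seq] == next(iter(truth_label[seq]))


def test_false_positive_curve_monotone_and_oracle(rng):
    ref = ReferenceSet("genome", {"chr": random_dna(rng, 5000)})
    curve, queries = false_positive_curve([18, 20], ref, k_values=[0, 1, 2, 3],
                                          n=300, seed=5, return_queries=True)
    fracs = curve["fraction_hit"].to_numpy()
    assert (np.diff(fracs) >= 0).all()
    # brute-force recomputation of the hit fractions on the same drawn queries
    expected = np.zeros(4)
    for q in queries:
        best = min((mm for *_, mm in oracle_hits(q, ref, 3)), default=99)
        for k in range(4):
            expected[k] += best <= k
    expected /= len(queries)
    assert np.allclose(fracs, expected)


def test_false_positive_curve_validation(rng):
    ref = ReferenceSet("g", {"c": random_dna(rng, 100)})
    with pytest.raises(ValueError):
        false_positive_curve([20], ref, [0], n=0, seed=1)
    with pytest.raises(ValueError, match="empty length"):
        false_positive_curve([], ref, [0], n=5, seed=1)
    single = false_positive_curve([20], ref, [0], n=1, seed=1)
    assert single["fraction_hit"].iloc[0] in (0.0, 1.0)
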