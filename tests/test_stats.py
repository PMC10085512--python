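"""Composition, PCA and yield-loss regression: oracles and recovery."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from pacseq import (
    EvidenceFilter,
    composition,
    fit_yield_loss,
    make_counts,
    make_pac,
    pac_norm,
    pca_counts,
    read_pac,
    variance_vs_contamination,
    write_pac,
)
from pacseq.stats import YieldLossModel, yield_loss_curve
from tests.conftest import random_dna


def pac_with_classes(counts_by_class):
    """One-sample PAC whose sequences carry a 'cls' annotation column."""
    seqs, classes, cnts = [], [], {}
    rng = np.random.default_rng(0)
    for cls, class_counts in counts_by_class.items():
        for c in class_counts:
            s = random_dna(rng, 20)
            seqs.append(s)
            classes.append(cls)
            cnts[s] = c
    pac = make_pac(pd.DataFrame({"sample_id": ["s"]}),
                   make_counts({"s": Counter(cnts)}, EvidenceFilter(1, 1)))
    pac.anno["cls"] = pd.Series(dict(zip(seqs, classes))).reindex(pac.anno.index)
    return pac


def test_composition_single_class_is_one():
    pac = pac_with_classes({"only": [5, 7, 3]})
    comp = composition(pac, "cls")
    assert comp.loc["s", "only"] == 1.0


def test_composition_read_weighted_fractions():
    pac = pac_with_classes({"a": [10, 20], "b": [70]})
    comp = composition(pac, "cls")
    assert comp.loc["s", "a"] == pytest.approx(0.3)
    assert comp.loc["s", "b"] == pytest.approx(0.7)
    assert comp.loc["s", "total"] == 100


def test_composition_matches_groupby_oracle(rng):
    per = {f"s{j}": Counter({random_dna(rng, 18): int(rng.integers(1, 30))
                             for _ in range(25)}) for j in range(3)}
    pac = make_pac(pd.DataFrame({"sample_id": list(per)}),
                   make_counts(per, EvidenceFilter(1, 1)))
    classes = ["x", "y", "z"]
    pac.anno["cls"] = [classes[i % 3] for i in range(len(pac.anno))]
    comp = composition(pac, "cls", weight="reads")
    for j in per:
        total = pac.counts[j].sum()
        for cls in classes:
            mask = pac.anno["cls"] == cls
            assert comp.loc[j, cls] == pytest.approx(
                pac.counts.loc[mask, j].sum() / total)
    frac = comp[classes].to_numpy()
    assert np.allclose(frac.sum(axis=1), 1.0)


def test_composition_missing_column(rng):
    pac = pac_with_classes({"a": [1, 2]})
    with pytest.raises(ValueError, match="not present"):
        composition(pac, "nope")


def random_multi_sample_pac(rng, n_samples=12, n_seqs=50):
    per = {f"s{j:02d}": Counter({random_dna(rng, 20): int(rng.integers(1, 200))
                                 for _ in range(n_seqs)}) for j in range(n_samples)}
    pheno = pd.DataFrame({"sample_id": list(per)})
    return make_pac(pheno, make_counts(per, EvidenceFilter(1, 1)))


def test_pca_rank1_two_group_construction(rng):
    """Two groups of identical samples: PC1 carries all the variance."""
    a = Counter({random_dna(rng, 20): int(rng.integers(10, 100)) for _ in range(30)})
    b = Counter({random_dna(rng, 20): int(rng.integers(10, 100)) for _ in range(30)})
    per = {"a1": a, "a2": a, "a3": a, "b1": b, "b2": b, "b3": b}
    pac = make_pac(pd.DataFrame({"sample_id": list(per)}),
                   make_counts(per, EvidenceFilter(1, 1)))
    res = pca_counts(pac)
    assert res.var_explained[0] == pytest.approx(1.0, abs=1e-10)
    pc1 = res.scores["PC1"]
    assert np.sign(pc1[["a1", "a2", "a3"]]).nunique() == 1
    assert (np.sign(pc1["a1"]) != np.sign(pc1["b1"]))


def test_pca_matches_eigendecomposition_oracle(rng):
    """var_explained and scores agree with a direct covariance eigensolve."""
    pac = random_multi_sample_pac(rng)
    res = pca_counts(pac)
    X = np.log2(pac_norm(pac).to_numpy().T + 1)
    Xc = X - X.mean(axis=0)
    C = Xc @ Xc.T  # sample-space Gram matrix shares nonzero eigenvalues
    evals = np.sort(np.linalg.eigvalsh(C))[::-1]
    total = evals.sum()
    r = res.n_components
    assert np.allclose(res.var_explained, evals[:r] / total, atol=1e-8)
    # scores reproduce the centered matrix: X_c ~ scores @ loadings^T
    approx = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(approx, Xc, atol=1e-8)


def test_pca_sign_convention_and_roundtrip_determinism(rng, tmp_path):
    pac = random_multi_sample_pac(rng)
    res1 = pca_counts(pac)
    for j in range(res1.n_components):
        col = res1.loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0
    write_pac(pac, tmp_path / "pac")
    res2 = pca_counts(read_pac(tmp_path / "pac"))
    assert np.array_equal(res1.scores.to_numpy(), res2.scores.to_numpy())


def test_pca_requires_two_samples():
    pac = pac_with_classes({"a": [3, 4]})
    with pytest.raises(ValueError, match="2 samples"):
        pca_counts(pac)


def test_yield_loss_zero_noise_recovery():
    I, A = 50.0, 10.0
    x = np.arange(0, 1.0, 0.1)
    y = yield_loss_curve(x, I, A)
    res = fit_yield_loss(x, y)
    assert res.I == pytest.approx(I, rel=1e-6)
    assert res.A == pytest.approx(A, rel=1e-6)
    assert res.converged and res.rss < 1e-12


def test_yield_loss_curve_form():
    assert yield_loss_curve(0.0, 123.0, 4.0) == 0.0
    # slope at zero is I; asymptote is A
    eps = 1e-9
    assert yield_loss_curve(eps, 50.0, 10.0) / eps == pytest.approx(50.0, rel=1e-6)
    assert yield_loss_curve(1e9, 50.0, 10.0) == pytest.approx(10.0, rel=1e-6)


def test_yield_loss_fit_order_invariant():
    rng = np.random.default_rng(1)
    x = np.linspace(0, 0.9, 10)
    y = yield_loss_curve(x, 30.0, 8.0) + rng.normal(0, 0.2, x.size)
    res1 = fit_yield_loss(x, y)
    perm = rng.permutation(x.size)
    res2 = fit_yield_loss(x[perm], y[perm])
    assert res1.I == pytest.approx(res2.I) and res1.A == pytest.approx(res2.A)


def test_yield_loss_monte_carlo_recovery():
    """Median estimates over noisy replicates stay within 5% of truth."""
    I, A, sigma = 50.0, 10.0, 0.5  # sigma = 5% of A
    x = np.arange(0, 1.0, 0.1)
    rng = np.random.default_rng(7)
    Is, As = [], []
    for _ in range(200):
        y = yield_loss_curve(x, I, A) + rng.normal(0, sigma, x.size)
        res = fit_yield_loss(x, y)
        Is.append(res.I)
        As.append(res.A)
    assert abs(np.median(Is) - I) / I < 0.05
    assert abs(np.median(As) - A) / A < 0.05


def test_yield_loss_degenerate_designs():
    with pytest.raises(ValueError, match="identical"):
        YieldLossModel([0.5, 0.5, 0.5], [1, 2, 3])
    with pytest.raises(ValueError, match="3 distinct"):
        YieldLossModel([0.1, 0.1, 0.5], [1, 2, 3])


def test_yield_loss_summary_mentions_parameters():
    x = np.arange(0, 1.0, 0.1)
    res = fit_yield_loss(x, yield_loss_curve(x, 20.0, 5.0))
    text = res.summary()
    assert "I (initial slope)" in text and "A (asymptote)" in text


def test_variance_vs_contamination_degenerate(rng):
    pac = random_multi_sample_pac(rng, n_samples=5)
    res = pca_counts(pac)
    out = variance_vs_contamination(res, pd.Series(0.3, index=res.scores.index))
    assert out.degenerate and out.fit is None and np.isnan(out.correlation)


def test_variance_vs_contamination_orientation(rng):
    pac = random_multi_sample_pac(rng, n_samples=8)
    res = pca_counts(pac)
    contam = pd.Series(np.linspace(0, 0.7, 8), index=res.scores.index)
    out = variance_vs_contamination(res, contam)
    assert out.correlation >= 0
    flipped = res
    flipped.scores["PC1"] *= -1
    out2 = variance_vs_contamination(flipped, contam)
    assert out2.correlation == pytest.approx(out.correlation)


def test_variance_vs_contamination_sample_mismatch(rng):
    pac = random_multi_sample_pac(rng, n_samples=5)
    res = pca_counts(pac)
    bad = pd.Series(0.1, index=[f"x{i}" for i in range(5)])
    with pytest.raises(ValueError, match="does not match"):
        variance_vs_contamination(res, bad)
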