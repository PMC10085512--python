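"""Composition summaries, PCA and the yield-loss contamination model.

Keeping every sequence — aligned or not — makes contamination measurable
rather than invisible.  Three views are provided:

* :func:`composition` — per-sample class proportions (reads- or
  unique-sequence-weighted) from any annotation column;
* :func:`pca_counts` — PCA of log2(CPM + 1) with samples as observations,
  quantifying how much of the between-sample variance a contaminant
  explains;
* :class:`YieldLossModel` — the rectangular hyperbola of weed-science yield
  loss, ``y = I*x / (1 + I*x/A)``, fitted by nonlinear least squares.  When
  x is the contamination fraction of a library and y a sample-level
  response (e.g. its PC1 score), I is the marginal effect of the first
  trace of contamination and A the saturation plateau — small contaminant
  fractions do disproportionate damage, exactly as low weed densities do to
  crop yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from pacseq.pac import PACObject, pac_norm


# ---------------------------------------------------------------------------
# composition

def composition(pac: PACObject, class_column: str,
                weight: str = "reads") -> pd.DataFrame:
    """Per-sample fractions of each annotation class.

    ``weight="reads"``: fraction of each library's reads carried by each
    class.  ``weight="sequences"``: fraction of unique sequences per class
    (identical across samples only if all sequences occur everywhere; here
    computed per sample over sequences with nonzero count).  Rows are
    samples, columns classes; each row sums to 1.  A ``total`` column
    carries the per-sample denominator.
    """
    if class_column not in pac.anno.columns:
        raise ValueError(f"annotation column {class_column!r} not present")
    classes = pac.anno[class_column].astype(str)
    if weight == "reads":
        grouped = pac.counts.groupby(classes).sum().T  # samples x classes
    elif weight == "sequences":
        present = (pac.counts > 0).astype(int)
        grouped = present.groupby(classes).sum().T
    else:
        raise ValueError("weight must be 'reads' or 'sequences'")
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(f"samples with zero total: {list(totals[totals == 0].index)}")
    frac = grouped.div(totals, axis=0)
    frac["total"] = totals
    frac.index.name = "sample_id"
    return frac


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    """Scores (samples x PCs), loadings (sequences x PCs), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_counts(pac: PACObject, n_components: int | None = None) -> PCAResult:
    """PCA of the sample x sequence matrix of log2(CPM + 1).

    Samples are observations; the matrix is column-centered (per-sequence)
    and not scaled.  Computed by SVD; deterministic up to sign, which is
    fixed so each loading vector's largest-magnitude element is positive.
    ``var_explained`` is squared singular values over total variance, so it
    sums to 1 over the full rank.
    """
    if pac.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if pac.n_sequences < 2:
        raise ValueError("PCA needs at least 2 sequences")
    X = np.log2(pac_norm(pac).to_numpy().T + 1.0)  # samples x sequences
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    if total_var == 0.0:
        raise ValueError("zero total variance: all samples identical")
    r = min(len(S), pac.n_samples - 1)  # centering removes one dimension
    if n_components is not None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        r = min(r, n_components)
    U, S, Vt = U[:, :r], S[:r], Vt[:r]
    # sign convention: largest-|loading| element of each PC positive
    for j in range(r):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(r)]
    scores = pd.DataFrame(U * S, index=pac.pheno.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=pac.counts.index, columns=pcs)
    return PCAResult(scores=scores, loadings=loadings,
                     var_explained=S**2 / total_var)


# ---------------------------------------------------------------------------
# yield-loss regression

def yield_loss_curve(x, I, A):
    """Rectangular hyperbola y = I*x / (1 + I*x/A); y(0)=0, slope I at 0, asymptote A."""
    x = np.asarray(x, dtype=float)
    return I * x / (1.0 + I * x / A)


@dataclass
class YieldLossResults:
    """Fit of the yield-loss hyperbola; statsmodels-style results object."""

    I: float
    A: float
    rss: float
    converged: bool
    nobs: int
    x: np.ndarray
    y: np.ndarray

    def predict(self, x) -> np.ndarray:
        return yield_loss_curve(x, self.I, self.A)

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.predict(self.x)

    def summary(self) -> str:
        lines = [
            "Yield-loss regression   y = I*x / (1 + I*x/A)",
            "=" * 46,
            f"nobs        {self.nobs:>12d}",
            f"I (initial slope) {self.I:>14.6g}",
            f"A (asymptote)     {self.A:>14.6g}",
            f"RSS               {self.rss:>14.6g}",
            f"converged         {str(self.converged):>14s}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.x, self.y, s=18, label="samples")
        xs = np.linspace(0, max(self.x.max(), 1e-9), 200)
        ax.plot(xs, self.predict(xs), color="C1",
                label=f"I={self.I:.3g}, A={self.A:.3g}")
        ax.set_xlabel("contamination fraction")
        ax.set_ylabel("response")
        ax.legend()
        return ax


class YieldLossModel:
    """Nonlinear least squares for the rectangular-hyperbola yield-loss model.

    Requires at least 3 distinct x values.  The fit is invariant to sample
    order; A is constrained positive.  Optimization restarts from three
    deterministic initializations (I0 from the low-x slope, A0 from the
    response magnitude, plus up/down-scaled variants); best RSS wins.
    """

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not np.isfinite(x).all() or not np.isfinite(y).all():
            raise ValueError("x and y must be finite")
        if np.unique(x).size < 2:
            raise ValueError("degenerate design: all x values identical")
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct x values")
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]

    def _initializations(self) -> list[tuple[float, float]]:
        x, y = self.x, self.y
        q1 = np.quantile(x, 0.25)
        low = x <= q1
        if low.sum() >= 2 and np.ptp(x[low]) > 0:
            slope = float(np.polyfit(x[low], y[low], 1)[0])
        else:
            nz = x > 0
            slope = float(np.median(y[nz] / x[nz])) if nz.any() else 1.0
        I0 = slope if abs(slope) > 1e-12 else 1.0
        A0 = float(np.max(np.abs(y)))
        if A0 <= 0:
            A0 = 1.0
        return [(I0, A0), (0.5 * I0, 2.0 * A0), (2.0 * I0, 0.5 * A0)]

    def fit(self) -> YieldLossResults:
        x, y = self.x, self.y

        def residuals(theta):
            return yield_loss_curve(x, theta[0], theta[1]) - y

        best = None
        for I0, A0 in self._initializations():
            sol = least_squares(
                residuals, x0=[I0, A0],
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        rss, sol = best
        return YieldLossResults(
            I=float(sol.x[0]), A=float(sol.x[1]), rss=rss,
            converged=bool(sol.status > 0), nobs=x.size, x=x, y=y,
        )


def fit_yield_loss(x: Sequence[float], y: Sequence[float]) -> YieldLossResults:
    """Functional wrapper: fit the yield-loss hyperbola to (x, y)."""
    return YieldLossModel(x, y).fit()


# ---------------------------------------------------------------------------
# PC1 vs contamination

@dataclass
class ContaminationEffect:
    """PC1-vs-contamination analysis: orientation-fixed correlation + fit."""

    correlation: float
    fit: YieldLossResults | None
    pc1: pd.Series
    degenerate: bool = False


def variance_vs_contamination(pca: PCAResult,
                              contamination: pd.Series | Sequence[float]
                              ) -> ContaminationEffect:
    """Correlate PC1 scores with per-sample contamination and fit yield loss.

    PC1 orientation is chosen so its correlation with contamination is
    non-negative before fitting (a PC's sign is arbitrary).  Constant
    contamination gives an explicit degenerate result rather than an error.
    """
    pc1 = pca.scores["PC1"]
    if isinstance(contamination, pd.Series):
        if set(contamination.index) != set(pc1.index):
            raise ValueError("contamination index does not match PCA samples")
        contam = contamination.loc[pc1.index].to_numpy(dtype=float)
    else:
        contam = np.asarray(contamination, dtype=float)
        if contam.shape[0] != pc1.shape[0]:
            raise ValueError("contamination length does not match PCA samples")
    if np.ptp(contam) == 0 or np.std(pc1.to_numpy()) == 0:
        return ContaminationEffect(correlation=float("nan"), fit=None, pc1=pc1,
                                   degenerate=True)
    r = float(np.corrcoef(contam, pc1.to_numpy())[0, 1])
    if r < 0:
        pc1 = -pc1
        r = -r
    fit = None
    if np.unique(contam).size >= 3:
        # anchor the response at the uncontaminated state so y(0)=0 is meaningful
        baseline = float(pc1.to_numpy()[np.argmin(contam)])
        fit = YieldLossModel(contam, pc1.to_numpy() - baseline).fit()
    return ContaminationEffect(correlation=r, fit=fit, pc1=pc1)
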