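"""Feature-encoding model fits and derived statistics.

The elastic net minimizes

    (1/2N) * sum_i (y_i - b0 - x_i' b)^2
        + lambda * sum_j [ (1-alpha)/2 * b_j^2 + alpha * |b_j| ]

on z-scored columns and response, with an unpenalized intercept. alpha = 0.2
(modest sparsification, approaching ridge) and lambda = 0.9 / 0.8 for
complex- / simple-spike analyses are the working defaults; lambda = 0 reduces
to ordinary least squares, used for imaging responses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

from .core import TimeSeries, SpikeTrain
from .design import RegressorMatrix, KernelSpec
from .spikes import rate_from_train

__all__ = ["PenaltySpec", "EncodingFit", "ElasticNetEncoder", "fit_ols",
           "fit_elastic_net", "select_lambda", "classify_phenotype",
           "category_fraction", "decompose_calcium", "PHENOTYPE_LABELS"]

PHENOTYPE_LABELS = ("motion_onset", "rotational_velocity", "luminance",
                    "motor", "motion_duration")

#: fixed order used to break category ties deterministically
_CATEGORY_ORDER = ("motion_onset", "rotation", "luminance", "swim", "eye",
                   "motion_duration", "motion_velocity")

#: subcategory -> phenotype label collapse
_SUBCAT_TO_PHENOTYPE = {
    "motion_onset": "motion_onset",
    "rotation": "rotational_velocity",
    "luminance": "luminance",
    "swim": "motor",
    "eye": "motor",
    "motion_duration": "motion_duration",
    # graded translational speed collapses onto the duration phenotype:
    # both are sustained translational-motion features
    "motion_velocity": "motion_duration",
}


@dataclass
class PenaltySpec:
    alpha: float = 0.2
    lam: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class EncodingFit:
    """Per-regressor coefficients plus derived summaries of one fit."""

    names: list
    coefficients: np.ndarray
    intercept: float
    r_squared: float
    categories: dict
    rank_deficient: bool = False
    ambiguous: bool = False

    @property
    def nonzero_count(self) -> int:
        return int(np.sum(self.coefficients != 0))

    @property
    def normalized_weights(self) -> np.ndarray:
        a = np.abs(self.coefficients)
        s = a.sum()
        return a / s if s > 0 else a

    @property
    def category_fractions(self) -> dict:
        w = self.normalized_weights
        out: dict = {}
        for name, wi in zip(self.names, w):
            group, sub = self.categories[name]
            out[group] = out.get(group, 0.0) + wi
            out[sub] = out.get(sub, 0.0) + wi
        return out

    @property
    def best_regressor(self) -> str | None:
        w = self.normalized_weights
        if w.sum() == 0:
            return None
        return self.names[int(np.argmax(w))]

    @property
    def best_category(self) -> str | None:
        best = self.best_regressor
        return None if best is None else self.categories[best][1]


def _zscore(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (a - mu) / safe, sd


class ElasticNetEncoder(RegressorMixin, BaseEstimator):
    """Encoding regression on z-scored columns and response.

    ``lam = 0`` gives the ordinary-least-squares fit used for calcium
    responses; ``lam > 0`` the elastic-net fit used for spike rates. Fitted
    attributes: ``coef_`` (z-scored scale), ``intercept_``, ``r_squared_``,
    and ``summary_`` (an :class:`EncodingFit`).
    """

    def __init__(self, alpha: float = 0.2, lam: float = 0.0,
                 tol: float = 1e-8, max_iter: int = 100_000):
        self.alpha = alpha
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "ElasticNetEncoder":
        PenaltySpec(self.alpha, self.lam)  # validate
        names, cats, A = _coerce_design(X)
        y = np.asarray(getattr(y, "data", y), dtype=float).ravel()
        if A.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        Az, col_sd = _zscore(A)
        yz, y_sd = _zscore(y[:, None])
        yz = yz.ravel()

        rank_deficient = False
        if self.lam == 0:
            rank = np.linalg.matrix_rank(Az)
            rank_deficient = rank < min(Az.shape)
            model = LinearRegression().fit(Az, yz)
            coef = model.coef_.copy()
            if rank_deficient:  # flagged pseudoinverse solution
                coef = np.linalg.pinv(Az) @ (yz - yz.mean())
            intercept = float(yz.mean() - Az.mean(axis=0) @ coef)
        else:
            model = ElasticNet(alpha=self.lam, l1_ratio=self.alpha,
                               tol=self.tol, max_iter=self.max_iter,
                               fit_intercept=True)
            model.fit(Az, yz)
            coef = model.coef_.copy()
            intercept = float(model.intercept_)
        # columns with zero variance carry no information
        coef[col_sd == 0] = 0.0

        resid = yz - (Az @ coef + intercept)
        tss = np.sum((yz - yz.mean()) ** 2)
        self.coef_ = coef
        self.intercept_ = intercept
        self.r_squared_ = float(1.0 - np.sum(resid ** 2) / tss) if tss > 0 else 0.0
        self.names_ = names
        self.y_scale_ = float(y_sd.ravel()[0])
        self.summary_ = EncodingFit(names=names, coefficients=coef,
                                    intercept=intercept,
                                    r_squared=self.r_squared_,
                                    categories=cats,
                                    rank_deficient=rank_deficient)
        return self

    def predict(self, X) -> np.ndarray:
        _, _, A = _coerce_design(X)
        Az, _ = _zscore(A)
        return Az @ self.coef_ + self.intercept_


def _coerce_design(X) -> tuple[list, dict, np.ndarray]:
    if isinstance(X, RegressorMatrix):
        return X.names, dict(X.categories), X.values
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    names = [f"x{j}" for j in range(A.shape[1])]
    cats = {n: ("sensory", "motion_onset") for n in names}
    return names, cats, A


def fit_ols(y, X) -> EncodingFit:
    """Least-squares encoding fit on z-scored columns."""
    return ElasticNetEncoder(lam=0.0).fit(X, y).summary_


def fit_elastic_net(y, X, penalty: PenaltySpec | None = None) -> EncodingFit:
    """Elastic-net encoding fit at the given penalty (solver tolerance well
    below 1e-6 relative objective)."""
    p = penalty or PenaltySpec()
    return ElasticNetEncoder(alpha=p.alpha, lam=p.lam).fit(X, y).summary_


def elastic_net_objective(A: np.ndarray, y: np.ndarray, coef: np.ndarray,
                          intercept: float, alpha: float, lam: float) -> float:
    """The penalized objective value (for solver/oracle comparisons)."""
    resid = y - intercept - A @ coef
    pen = np.sum((1 - alpha) / 2 * coef ** 2 + alpha * np.abs(coef))
    return float(np.sum(resid ** 2) / (2 * len(y)) + lam * pen)


def select_lambda(signals, X, grid, penalty_alpha: float = 0.2,
                  method: str = "cv", n_splits: int = 5, seed: int = 0) -> float:
    """Penalty strength minimizing the summed RMSE over all signals.

    ``method='cv'`` (default) scores K-fold out-of-fold predictions, the
    reading under which shrinkage can win; ``method='insample'`` scores the
    training residuals. Ties prefer the larger (sparser) lambda.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid or not len(signals):
        raise ValueError("need a non-empty grid and at least one signal")
    _, _, A = _coerce_design(X)
    scores = np.zeros(len(grid))
    for i, lam in enumerate(grid):
        total = 0.0
        for y in signals:
            yarr = np.asarray(getattr(y, "data", y), dtype=float).ravel()
            if method == "cv":
                kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
                sq = 0.0
                for tr, te in kf.split(A):
                    enc = ElasticNetEncoder(alpha=penalty_alpha, lam=lam,
                                            tol=1e-6).fit(A[tr], yarr[tr])
                    # apply training-fold standardization to the test fold
                    mu, sd = A[tr].mean(0), A[tr].std(0)
                    sd = np.where(sd > 0, sd, 1.0)
                    ymu, ysd = yarr[tr].mean(), yarr[tr].std() or 1.0
                    pred = ((A[te] - mu) / sd) @ enc.coef_ + enc.intercept_
                    sq += np.sum((pred * ysd + ymu - yarr[te]) ** 2)
                total += np.sqrt(sq / len(yarr))
            else:
                enc = ElasticNetEncoder(alpha=penalty_alpha, lam=lam,
                                        tol=1e-6).fit(A, yarr)
                resid_var = (1 - enc.r_squared_) * np.var(
                    (yarr - yarr.mean()) / (yarr.std() or 1.0))
                total += np.sqrt(max(resid_var, 0.0))
        scores[i] = total
    best = np.flatnonzero(scores <= scores.min() + 1e-12)
    return grid[int(best.max())]  # ties -> larger lambda (sparser)


def classify_phenotype(fit: EncodingFit) -> str:
    """Phenotype label from the regressor with the largest normalized weight.

    Per-direction onset regressors collapse to ``motion_onset``, CW/CCW to
    ``rotational_velocity``, both luminance transitions to ``luminance``.
    Ties between categories are broken by summed category weight, then by a
    fixed category order; the fit is flagged ambiguous.
    """
    w = fit.normalized_weights
    if w.sum() == 0:
        return "unclassified"
    top = w.max()
    top_subs = {fit.categories[n][1] for n, wi in zip(fit.names, w)
                if np.isclose(wi, top)}
    if len(top_subs) == 1:
        return _SUBCAT_TO_PHENOTYPE[top_subs.pop()]
    fit.ambiguous = True
    sums = {s: 0.0 for s in top_subs}
    for n, wi in zip(fit.names, w):
        s = fit.categories[n][1]
        if s in sums:
            sums[s] += wi
    best = max(sums.values())
    tied = sorted(s for s, v in sums.items() if np.isclose(v, best))
    for s in _CATEGORY_ORDER:
        if s in tied:
            return _SUBCAT_TO_PHENOTYPE[s]
    return _SUBCAT_TO_PHENOTYPE[tied[0]]


def category_fraction(fit: EncodingFit, category: str) -> float:
    """Share of total |coefficient| weight carried by one category (a group
    like 'motor'/'sensory' or a subcategory like 'rotation')."""
    if np.abs(fit.coefficients).sum() == 0:
        raise ValueError("all-zero fit has no category fractions")
    return fit.category_fractions.get(category, 0.0)


def decompose_calcium(dff: TimeSeries, cs: SpikeTrain, ss: SpikeTrain,
                      kernel: KernelSpec | None = None,
                      rate_filter_width: float = 0.020) -> dict:
    """Relative CS/SS contribution to a calcium signal.

    Regresses dF/F on the kernel-convolved CS- and SS-rate regressors;
    the contribution percent of source s is |beta_s| * SD(regressor_s)
    normalized over sources. Degenerate cases (no spikes of one type) return
    a flagged 100/0 split.
    """
    kernel = kernel or KernelSpec()
    rate = dff.rate
    n = dff.n
    k = kernel.sample(rate)
    regs = []
    for train in (cs, ss):
        r = rate_from_train(train, rate, rate_filter_width,
                            duration=n / rate, t0=dff.t0).data
        regs.append(np.convolve(r, k)[:n])
    R = np.column_stack(regs)
    sds = R.std(axis=0)
    if np.any(sds == 0):
        pct = 100.0 if sds[0] > 0 else 0.0
        return {"cs_percent": pct, "ss_percent": 100.0 - pct, "flagged": True}
    A = np.column_stack([R, np.ones(n)])
    beta, *_ = np.linalg.lstsq(A, dff.data, rcond=None)
    contrib = np.abs(beta[:2]) * sds
    share = contrib / contrib.sum()
    return {"cs_percent": float(100 * share[0]),
            "ss_percent": float(100 * share[1]), "flagged": False}
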