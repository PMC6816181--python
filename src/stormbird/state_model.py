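"""Behavioral-state regression and between-event nonparametric tests.

The core model is a multinomial logistic regression of behavioral state on
weather covariates, fitted by Newton-Raphson on the multinomial logit
log-likelihood with the inactive state as the reference level.  With two
pooled states (inactive vs active, the form exercised here) it reduces
exactly to binary logistic regression.  The model set is always the four
specs {null, wind-only, pressure-only, global}; selection is by AIC
(2k - 2 logLik), with Delta-AIC < 2 flagged as co-best.  Odds ratios are
exp(beta) per unit increase and exp(-beta) per unit decrease.

Covariates are z-standardized within the event window by default; the
coefficient scale of the reported tables is only meaningful under
standardized predictors.  Observations are treated as independent across
fixes and individuals; serial autocorrelation is acknowledged, not
modelled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "SeparationError",
    "MNLFit",
    "TestResult",
    "MultinomialLogit",
    "fit_mnl",
    "model_set",
    "aic_select",
    "odds_ratio",
    "state_probability",
    "kruskal_wallis",
    "wilcoxon_ranksum",
    "coefficient_table",
]

MODEL_SPECS = {
    "null": [],
    "wind": ["wv_kmh"],
    "pressure": ["bp_kpa"],
    "global": ["bp_kpa", "wv_kmh"],
}


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges."""


@dataclass
class MNLFit:
    """Coefficients and fit metadata of one multinomial logit fit."""

    model: str
    covariates: list[str]
    coef: pd.DataFrame          # rows: Intercept + covariates; per-state columns
    se: pd.DataFrame
    tvalue: pd.DataFrame
    llf: float
    aic: float
    n: int
    k: int                      # free coefficients
    converged: bool
    standardized: bool
    scale_: dict = field(default_factory=dict)   # covariate -> (mean, sd)
    estimator: "MultinomialLogit | None" = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    group_sizes: tuple
    tie_corrected: bool
    method: str                 # 'asymptotic' | 'exact'
    z: float | None = None


class MultinomialLogit(ClassifierMixin, BaseEstimator):
    """Newton-Raphson multinomial logit with a reference state.

    Implemented for K >= 2 response levels; level 0 (inactive) is the
    reference.  ``coef_`` has shape (K-1, p) on the (optionally
    standardized) design including the intercept; standard errors come
    from the inverse observed information.

    Parameters
    ----------
    standardize : z-score the covariate columns before fitting.
    max_iter, tol_score, tol_llf : stopping rules — converged when the
        maximum absolute score component < tol_score or the relative
        log-likelihood change < tol_llf.
    beta_guard : coefficient-norm bound treated as evidence of perfect
        separation.
    """

    def __init__(self, standardize: bool = True, max_iter: int = 100,
                 tol_score: float = 1e-8, tol_llf: float = 1e-10,
                 beta_guard: float = 30.0):
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_llf = tol_llf
        self.beta_guard = beta_guard

    def _design(self, X, fit_scale: bool):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if fit_scale:
            if self.standardize and X.shape[1] > 0:
                self.scale_mean_ = X.mean(axis=0)
                self.scale_sd_ = X.std(axis=0, ddof=1)
                if np.any(self.scale_sd_ == 0):
                    raise ValueError("constant covariate cannot be standardized")
            else:
                self.scale_mean_ = np.zeros(X.shape[1])
                self.scale_sd_ = np.ones(X.shape[1])
        Z = (X - self.scale_mean_) / self.scale_sd_
        return np.column_stack([np.ones(len(Z)), Z])

    @staticmethod
    def _check_rank(D, names):
        r = np.linalg.matrix_rank(D)
        if r < D.shape[1]:
            _, _, piv = qr(D, pivoting=True)
            bad = [names[j] for j in piv[r:]]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    def _probs(self, D, B):
        eta = np.column_stack([np.zeros(len(D)), D @ B.T])   # reference eta = 0
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def _loglik(self, D, Y, B):
        P = self._probs(D, B)
        return float(np.sum(np.log(np.maximum(P[np.arange(len(Y)), Y], 1e-300))))

    def fit(self, X, y):
        y = np.asarray(y)
        classes, Y = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 observed states")
        self.classes_ = classes
        K = len(classes)
        D = self._design(X, fit_scale=True)
        names = ["Intercept"] + [f"x{j}" for j in range(D.shape[1] - 1)]
        if D.shape[0] <= D.shape[1] * (K - 1):
            raise ValueError("more coefficients than observations")
        self._check_rank(D, names)

        n, p = D.shape
        B = np.zeros((K - 1, p))
        ll = self._loglik(D, Y, B)
        self.converged_ = False
        for _ in range(self.max_iter):
            P = self._probs(D, B)
            # score and observed information over the stacked (K-1)*p params
            score = np.empty((K - 1, p))
            for k in range(1, K):
                score[k - 1] = D.T @ ((Y == k).astype(float) - P[:, k])
            Hm = np.empty(((K - 1) * p, (K - 1) * p))
            for k in range(1, K):
                for l in range(1, K):
                    w = P[:, k] * ((k == l) - P[:, l])
                    Hm[(k - 1) * p:k * p, (l - 1) * p:l * p] = D.T @ (w[:, None] * D)
            try:
                step = np.linalg.solve(Hm, score.ravel())
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hm, score.ravel(), rcond=None)[0]
            # damped Newton: halve until the log-likelihood improves
            t = 1.0
            for _ in range(30):
                Bn = B + t * step.reshape(K - 1, p)
                lln = self._loglik(D, Y, Bn)
                if lln >= ll - 1e-12:
                    break
                t /= 2.0
            B, ll_prev, ll = Bn, ll, lln
            if np.linalg.norm(B) > self.beta_guard * p * (K - 1):
                raise SeparationError("diverging coefficients: perfect separation")
            if (np.abs(score).max() < self.tol_score
                    or abs(ll - ll_prev) < self.tol_llf * max(1.0, abs(ll))):
                self.converged_ = True
                break

        P = self._probs(D, B)
        Hm = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(1, K):
                w = P[:, k] * ((k == l) - P[:, l])
                Hm[(k - 1) * p:k * p, (l - 1) * p:l * p] = D.T @ (w[:, None] * D)
        cov = np.linalg.inv(Hm)
        self.coef_ = B
        self.se_ = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(K - 1, p)
        self.llf_ = ll
        self.n_ = n
        self.k_ = (K - 1) * p
        self.aic_ = 2 * self.k_ - 2 * ll
        return self

    def predict_proba(self, X):
        D = self._design(X, fit_scale=False)
        return self._probs(D, self.coef_)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_vector(self, X, y):
        """Score (gradient) at the fitted optimum; ~0 at an interior MLE."""
        y = np.asarray(y)
        _, Y = np.unique(y, return_inverse=True)
        D = self._design(X, fit_scale=False)
        P = self._probs(D, self.coef_)
        K = len(self.classes_)
        return np.concatenate([D.T @ ((Y == k).astype(float) - P[:, k])
                               for k in range(1, K)])


def fit_mnl(states, covariates: pd.DataFrame | None, model: str = "custom",
            standardize: bool = True, state_names: list[str] | None = None) -> MNLFit:
    """Fit one multinomial logit spec and package the coefficient tables.

    ``states`` codes the response with 0 = the reference (inactive) level;
    ``covariates`` is a DataFrame of predictor columns (may be None/empty
    for the null model).
    """
    states = np.asarray(states)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        cov_names: list[str] = []
        X = np.empty((len(states), 0))
        est = MultinomialLogit(standardize=False)
    else:
        cov_names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
        est = MultinomialLogit(standardize=standardize)
    est.fit(X, states)

    classes = est.classes_
    if state_names is None:
        state_names = [str(c) for c in classes]
    rows = ["Intercept"] + cov_names
    cols = [state_names[i] for i in range(1, len(classes))]
    coef = pd.DataFrame(est.coef_.T, index=rows, columns=cols)
    se = pd.DataFrame(est.se_.T, index=rows, columns=cols)
    scale = {c: (float(est.scale_mean_[j]), float(est.scale_sd_[j]))
             for j, c in enumerate(cov_names)}
    return MNLFit(model=model, covariates=cov_names, coef=coef, se=se,
                  tvalue=coef / se, llf=est.llf_, aic=est.aic_, n=est.n_,
                  k=est.k_, converged=est.converged_,
                  standardized=standardize and bool(cov_names),
                  scale_=scale, estimator=est)


def model_set(data: pd.DataFrame, state_col: str = "state2",
              standardize: bool = True) -> dict[str, MNLFit]:
    """Fit the four-model set {null, wind, pressure, global} on one event."""
    out = {}
    for name, covs in MODEL_SPECS.items():
        cov_df = data[covs] if covs else None
        out[name] = fit_mnl(data[state_col].to_numpy(), cov_df, model=name,
                            standardize=standardize,
                            state_names=["inactive", "active"])
    return out


def aic_select(fits: dict[str, MNLFit], use_aicc: bool = False) -> pd.DataFrame:
    """Rank fits by (corrected) AIC; Delta < 2 marks co-best models."""
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits use different observation sets (n = {sorted(ns)}); "
                         "AIC values are not comparable")
    rows = []
    for name, f in fits.items():
        a = f.aic
        if use_aicc:
            a += 2 * f.k * (f.k + 1) / max(f.n - f.k - 1, 1)
        rows.append({"model": name, "k": f.k, "logLik": f.llf, "AIC": a})
    df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["co_best"] = df["dAIC"] < 2.0
    return df


def odds_ratio(fit: MNLFit, covariate: str, direction: str = "per-unit-increase",
               state: str | None = None) -> float:
    """exp(beta) for a unit increase, exp(-beta) for a unit decrease."""
    if covariate not in fit.coef.index:
        raise KeyError(f"{covariate!r} not in fitted model {fit.model!r}")
    col = state if state is not None else fit.coef.columns[0]
    beta = float(fit.coef.loc[covariate, col])
    if direction == "per-unit-increase":
        return math.exp(beta)
    if direction == "per-unit-decrease":
        return math.exp(-beta)
    raise ValueError("direction must be 'per-unit-increase' or 'per-unit-decrease'")


def state_probability(fit: MNLFit, covariate_values: dict | None = None) -> float:
    """Fitted probability of the active state at given covariate values.

    Values are taken on the fit's scale (standardized if the fit was);
    missing covariates default to 0, i.e. the within-window mean under
    standardization.
    """
    covariate_values = covariate_values or {}
    eta = float(fit.coef.iloc[0, 0])
    for c in fit.covariates:
        eta += float(fit.coef.loc[c, fit.coef.columns[0]]) * float(covariate_values.get(c, 0.0))
    return 1.0 / (1.0 + math.exp(-eta))


# ---------------------------------------------------------------- tests


def _kw_statistic(values: np.ndarray, sizes: list[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled values split by sizes."""
    ranks = stats.rankdata(values)
    n = len(values)
    idx = np.cumsum([0] + sizes)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[idx[g]:idx[g + 1]].sum() ** 2 / sizes[g] for g in range(len(sizes))
    ) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(*groups, method: str = "auto",
                   exact_n_limit: int = 12) -> TestResult:
    """Kruskal-Wallis test across >= 2 groups.

    H and the chi-square p come from ``scipy.stats.kruskal`` (tie-corrected,
    g-1 df).  For small pooled samples (total n <= ``exact_n_limit`` under
    ``method='auto'``, or ``method='exact'``) the p-value is instead the
    exact permutation tail P(H >= H_obs) over all group re-assignments.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, group_sizes=tuple(sizes),
                          tie_corrected=True, method="degenerate")
    h_obs, p_asym = stats.kruskal(*groups)
    use_exact = method == "exact" or (method == "auto" and n <= exact_n_limit)
    if not use_exact:
        return TestResult(statistic=float(h_obs), p_value=float(p_asym),
                          group_sizes=tuple(sizes), tie_corrected=True,
                          method="asymptotic")

    count = total = 0
    for assign in _partitions(n, sizes):
        h = _kw_statistic(pooled[assign], sizes)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return TestResult(statistic=float(h_obs), p_value=count / total,
                      group_sizes=tuple(sizes), tie_corrected=True,
                      method="exact")


def _partitions(n: int, sizes: list[int]):
    """All ordered partitions of range(n) into blocks of the given sizes."""

    def rec(avail: tuple, remaining: list[int]):
        if len(remaining) == 1:
            yield list(avail)
            return
        k = remaining[0]
        for block in itertools.combinations(avail, k):
            rest = tuple(i for i in avail if i not in set(block))
            for tail in rec(rest, remaining[1:]):
                yield list(block) + tail

    yield from rec(tuple(range(n)), sizes)


def wilcoxon_ranksum(a, b, method: str = "auto",
                     exact_comb_limit: int = 200_000) -> TestResult:
    """Two-sample Wilcoxon rank-sum test.

    The statistic is the tie-corrected normal-approximation Z (no
    continuity correction) for the rank sum of the first sample.  Under
    ``method='auto'`` the p-value switches to exact enumeration of all
    C(n, n1) group assignments when that count is manageable; the
    asymptotic two-sided normal p is used otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else (w_obs - mu) / math.sqrt(var)
    p_norm = 2.0 * stats.norm.sf(abs(z)) if var > 0 else 1.0

    n_comb = math.comb(n, n1)
    use_exact = method == "exact" or (method == "auto" and n_comb <= exact_comb_limit)
    if not use_exact:
        return TestResult(statistic=w_obs, p_value=float(min(p_norm, 1.0)),
                          group_sizes=(n1, n2), tie_corrected=tie_term > 0,
                          method="asymptotic", z=z)

    dev_obs = abs(w_obs - mu)
    count = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return TestResult(statistic=w_obs, p_value=count / n_comb,
                      group_sizes=(n1, n2), tie_corrected=tie_term > 0,
                      method="exact", z=z)


def coefficient_table(fits_by_event: dict[str, MNLFit],
                      chosen: dict[str, str] | None = None) -> pd.DataFrame:
    """Regression-table report: per event, rows Intercept / Barometric
    Pressure / Wind Speed with coefficient, SE, t-value and significance
    stars (two-sided normal reference; * p<0.05, ** p<0.001)."""
    pretty = {"Intercept": "Intercept", "bp_kpa": "Barometric Pressure",
              "wv_kmh": "Wind Speed"}
    rows = []
    for event, fit in fits_by_event.items():
        col = fit.coef.columns[0]
        for var in fit.coef.index:
            t = float(fit.tvalue.loc[var, col])
            p = 2.0 * stats.norm.sf(abs(t))
            stars = "**" if p < 0.001 else ("*" if p < 0.05 else "")
            rows.append({
                "event": event,
                "variable": pretty.get(var, var),
                "coefficient": round(float(fit.coef.loc[var, col]), 4),
                "std_error": round(float(fit.se.loc[var, col]), 4),
                "t_value": round(t, 4),
                "signif": stars,
            })
    return pd.DataFrame(rows, columns=["event", "variable", "coefficient",
                                       "std_error", "t_value", "signif"])
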