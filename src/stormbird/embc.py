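"""Expectation–Maximization binary Clustering (EMbC) of movement features.

EMbC discretizes (velocity, turning angle) pairs into the four quadrant
states LL, LH, HL, HH — low/high velocity crossed with low/high turning
angle — via a four-component Gaussian mixture whose components stay
anchored to the binary quadrant structure: after every EM iteration the
components are relabelled so the two lowest-speed components carry the
L velocity bit and, within each speed pair, the lower-turn component
carries the L turn bit.  Delimiters (one split value per variable) are
recovered after convergence as the equal-likelihood crossing of the
weighted low-group and high-group marginal Gaussians.

The four states map onto behaviors as LL = inactive (rest), LH = localized
search, HL = commuting, HH = dispersive search; the pooled binary scheme
is inactive = LL, active = everything else.

A post-hoc smoothing pass favours homogeneous behavioral bouts: any fix
whose two temporal neighbours share a label different from its own has its
posterior for the neighbours' label multiplied by a weight w and is
reassigned if the boosted posterior wins.  Runs of length >= 2 of a
minority label are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "STATE_NAMES",
    "BEHAVIOR_NAMES",
    "EMbC",
    "LabelSequence",
    "embc_fit",
    "smooth_labels",
    "pool_states",
    "activity_budget",
    "plot_state_scatter",
]

# state code = 2 * v_bit + theta_bit (bit 1 = high)
STATE_NAMES = ["LL", "LH", "HL", "HH"]
BEHAVIOR_NAMES = ["inactive", "localized search", "commuting", "dispersive search"]

_RIDGE = 1e-9


@dataclass
class LabelSequence:
    """Per-fix EMbC labelling with posteriors and pooled binary states."""

    labels: np.ndarray              # int codes 0..3 (LL, LH, HL, HH)
    posteriors: np.ndarray          # (n, 4), rows sum to 1
    delimiter_labels: np.ndarray    # quadrant code by delimiter position
    pooled: np.ndarray = field(init=False)  # 0 = inactive, 1 = active

    def __post_init__(self):
        self.pooled = (self.labels != 0).astype(int)

    def state_names(self) -> np.ndarray:
        return np.array(STATE_NAMES)[self.labels]


def _quadrant_codes(speed, turn, v_split, t_split):
    return (2 * (speed > v_split) + (turn > t_split)).astype(int)


class EMbC(ClusterMixin, BaseEstimator):
    """Binary-delimited four-state Gaussian mixture for (speed, turn) data.

    Parameters
    ----------
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    smoothing_weight : likelihood boost w for the single-point smoothing
        pass (w = 1 disables smoothing).
    random_state : seed reserved for stochastic restarts; the default
        median-delimiter initialization is deterministic.

    Attributes (after ``fit``)
    --------------------------
    means_ : (4, 2) component means in state-code order LL, LH, HL, HH.
    covariances_ : (4, 2, 2); weights_ : (4,).
    delimiters_ : (velocity split km/h, turn split rad).
    labels_, posteriors_ : training-set labelling (pre-smoothing).
    loglik_trace_ : per-iteration log-likelihood, non-decreasing.
    converged_ : bool.
    """

    def __init__(self, max_iter: int = 300, tol: float = 1e-9,
                 smoothing_weight: float = 2.0, random_state: int | None = None):
        self.max_iter = max_iter
        self.tol = tol
        self.smoothing_weight = smoothing_weight
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _moments(self, X, resp):
        nk = resp.sum(axis=0)
        means = np.zeros((4, 2))
        covs = np.zeros((4, 2, 2))
        for k in range(4):
            if nk[k] < 1e-10:
                continue
            means[k] = resp[:, k] @ X / nk[k]
            d = X - means[k]
            covs[k] = (resp[:, k, None] * d).T @ d / nk[k] + _RIDGE * np.eye(2)
        return nk / len(X), means, covs

    def _log_prob(self, X, weights, means, covs):
        lp = np.empty((len(X), 4))
        for k in range(4):
            lp[:, k] = multivariate_normal.logpdf(X, means[k], covs[k],
                                                  allow_singular=True)
        return lp + np.log(np.maximum(weights, 1e-300))

    @staticmethod
    def _reorder(weights, means, covs):
        """Permute components onto the quadrant code order LL, LH, HL, HH."""
        by_speed = np.argsort(means[:, 0], kind="stable")
        lo, hi = by_speed[:2], by_speed[2:]
        lo = lo[np.argsort(means[lo, 1], kind="stable")]
        hi = hi[np.argsort(means[hi, 1], kind="stable")]
        perm = np.concatenate([lo, hi])  # -> LL, LH, HL, HH
        return weights[perm], means[perm], covs[perm]

    @staticmethod
    def _marginal_crossing(weights, means, sds, lo_idx, hi_idx, axis_vals):
        """Equal-likelihood crossing of the weighted low vs high marginals."""

        def diff(x):
            lo = sum(weights[k] * np.exp(-0.5 * ((x - means[k]) / sds[k]) ** 2)
                     / sds[k] for k in lo_idx)
            hi = sum(weights[k] * np.exp(-0.5 * ((x - means[k]) / sds[k]) ** 2)
                     / sds[k] for k in hi_idx)
            return lo - hi

        a = float(np.average(means[lo_idx], weights=np.maximum(weights[lo_idx], 1e-12)))
        b = float(np.average(means[hi_idx], weights=np.maximum(weights[hi_idx], 1e-12)))
        if b <= a:
            return 0.5 * (a + b)
        try:
            if diff(a) * diff(b) < 0:
                return float(brentq(diff, a, b))
        except ValueError:
            pass
        return 0.5 * (a + b)

    # -- API -----------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ok = np.all(np.isfinite(X), axis=1)
        Xf = X[ok]
        if len(Xf) < 40:
            raise ValueError("EMbC needs at least 40 complete feature pairs")
        if np.any(Xf[:, 0] < 0):
            raise ValueError("speeds must be non-negative")
        if np.any((Xf[:, 1] < 0) | (Xf[:, 1] > np.pi + 1e-9)):
            raise ValueError("turning angles must lie in [0, pi]")

        v_split = float(np.median(Xf[:, 0]))
        t_split = float(np.median(Xf[:, 1]))
        codes = _quadrant_codes(Xf[:, 0], Xf[:, 1], v_split, t_split)
        resp = np.zeros((len(Xf), 4))
        resp[np.arange(len(Xf)), codes] = 1.0
        weights, means, covs = self._moments(Xf, resp)
        gmean, gcov = Xf.mean(axis=0), np.cov(Xf.T) + _RIDGE * np.eye(2)
        for k in range(4):
            if weights[k] < 1e-9:
                warnings.warn(f"empty quadrant {STATE_NAMES[k]} at initialization; "
                              "reseeded at global moments")
                means[k], covs[k], weights[k] = gmean, gcov, 1e-3
        weights /= weights.sum()
        weights, means, covs = self._reorder(weights, means, covs)

        trace = []
        self.converged_ = False
        for _ in range(self.max_iter):
            lp = self._log_prob(Xf, weights, means, covs)
            m = lp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(lp - m).sum(axis=1))
            ll = float(lse.sum())
            if trace and ll < trace[-1] - 1e-8:
                raise RuntimeError("EM log-likelihood decreased")
            resp = np.exp(lp - lse[:, None])
            weights, means, covs = self._moments(Xf, resp)
            for k in range(4):
                if weights[k] < 1e-9:
                    means[k], covs[k], weights[k] = gmean, gcov, 1e-3
            weights /= weights.sum()
            weights, means, covs = self._reorder(weights, means, covs)
            if trace and abs(ll - trace[-1]) <= self.tol * max(1.0, abs(ll)):
                trace.append(ll)
                self.converged_ = True
                break
            trace.append(ll)
        if not self.converged_:
            warnings.warn("EMbC did not converge within max_iter")

        self.weights_, self.means_, self.covariances_ = weights, means, covs
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)

        sds_v = np.sqrt(covs[:, 0, 0])
        sds_t = np.sqrt(covs[:, 1, 1])
        self.delimiters_ = (
            self._marginal_crossing(weights, means[:, 0], sds_v, [0, 1], [2, 3], Xf[:, 0]),
            self._marginal_crossing(weights, means[:, 1], sds_t, [0, 2], [1, 3], Xf[:, 1]),
        )

        seq = self.label(X)
        self.labels_ = seq.labels
        self.posteriors_ = seq.posteriors
        return self

    def label(self, X) -> LabelSequence:
        """Label feature pairs by posterior; undefined turns fall back to the
        velocity delimiter alone (low turn bit by convention)."""
        X = np.asarray(X, dtype=float)
        post = np.zeros((len(X), 4))
        labels = np.zeros(len(X), dtype=int)
        ok = np.all(np.isfinite(X), axis=1)
        if ok.any():
            lp = self._log_prob(X[ok], self.weights_, self.means_, self.covariances_)
            m = lp.max(axis=1, keepdims=True)
            p = np.exp(lp - m)
            post[ok] = p / p.sum(axis=1, keepdims=True)
            labels[ok] = post[ok].argmax(axis=1)
        if (~ok).any():
            hi_v = X[~ok, 0] > self.delimiters_[0]
            labels[~ok] = np.where(hi_v, 2, 0)      # HL / LL by velocity only
            post[~ok, labels[~ok]] = 1.0
        dl = _quadrant_codes(np.nan_to_num(X[:, 0]),
                             np.nan_to_num(X[:, 1]),
                             self.delimiters_[0], self.delimiters_[1])
        return LabelSequence(labels=labels, posteriors=post, delimiter_labels=dl)

    def predict(self, X):
        return self.label(X).labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def embc_fit(features, max_iter: int = 300, tol: float = 1e-9,
             seed: int | None = None) -> tuple[EMbC, LabelSequence]:
    """Fit EMbC on an (n, 2) array of (speed km/h, turn rad) pairs."""
    model = EMbC(max_iter=max_iter, tol=tol, random_state=seed).fit(features)
    return model, model.label(np.asarray(features, dtype=float))


def smooth_labels(seq: LabelSequence, w: float = 2.0,
                  burst_ids: np.ndarray | None = None) -> LabelSequence:
    """Single-point smoothing: repair isolated labels inside homogeneous bouts.

    For every fix whose two temporal neighbours (within the same burst)
    share a label different from its own, the posterior for the neighbours'
    label is multiplied by ``w``; the fix is reassigned when the boosted
    posterior exceeds its current label's posterior.  One forward pass over
    the original labels; idempotent on its own output and incapable of
    touching any minority run of length >= 2.
    """
    if w < 1:
        raise ValueError("smoothing weight must be >= 1")
    labels = seq.labels.copy()
    n = len(labels)
    if burst_ids is None:
        burst_ids = np.zeros(n, dtype=int)
    orig = seq.labels
    # forward pass: the left neighbour reflects flips already made, so
    # alternating single-point patterns resolve in one sweep
    for i in range(1, n - 1):
        if burst_ids[i - 1] != burst_ids[i] or burst_ids[i + 1] != burst_ids[i]:
            continue
        if labels[i - 1] == orig[i + 1] != labels[i]:
            nb = labels[i - 1]
            if w * seq.posteriors[i, nb] > seq.posteriors[i, labels[i]]:
                labels[i] = nb
    return LabelSequence(labels=labels, posteriors=seq.posteriors.copy(),
                         delimiter_labels=seq.delimiter_labels.copy())


def pool_states(labels: np.ndarray) -> np.ndarray:
    """Pool the four EMbC states to binary: 0 = inactive (LL), 1 = active."""
    return (np.asarray(labels) != 0).astype(int)


def activity_budget(pooled_by_individual: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-individual activity percentages plus the cohort mean +/- SD row.

    Reporting convention: percentages are computed per individual first and
    then averaged, so the cohort active and inactive means need not sum to
    exactly 100 after rounding.
    """
    rows = []
    for ind, pooled in pooled_by_individual.items():
        pooled = np.asarray(pooled)
        if len(pooled) == 0:
            raise ValueError(f"individual {ind!r} has no labeled fixes")
        pct = 100.0 * float(np.mean(pooled == 1))
        rows.append({"individual_id": ind, "n_fixes": len(pooled),
                     "active_pct": pct, "inactive_pct": 100.0 - pct})
    df = pd.DataFrame(rows)
    k = len(df)
    cohort = {"individual_id": "cohort_mean", "n_fixes": int(df["n_fixes"].sum()),
              "active_pct": float(df["active_pct"].mean()),
              "inactive_pct": float(df["inactive_pct"].mean()),
              "active_sd": float(df["active_pct"].std(ddof=1)) if k > 1 else 0.0,
              "inactive_sd": float(df["inactive_pct"].std(ddof=1)) if k > 1 else 0.0}
    return pd.concat([df, pd.DataFrame([cohort])], ignore_index=True)


def plot_state_scatter(model: EMbC, X, labels, path) -> None:
    """Speed x turn scatter coloured by state with delimiter lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    X = np.asarray(X, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = ["#555555", "#1b9e77", "#7570b3", "#d95f02"]
    for k in range(4):
        m = labels == k
        ax.scatter(X[m, 0], X[m, 1], s=8, c=colors[k],
                   label=f"{STATE_NAMES[k]} ({BEHAVIOR_NAMES[k]})")
    ax.axvline(model.delimiters_[0], color="grey", lw=1)
    ax.axhline(model.delimiters_[1], color="grey", lw=1)
    ax.set_xlabel("velocity (km/h)")
    ax.set_ylabel("turning angle (rad)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
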