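"""Statistical machinery: Mann-Kendall trend test, logistic trend fits,
one-way ANOVA with Tukey HSD and compact letters, and a standardized
three-variable PCA.

These are the primitives every downstream trend and summary analysis is
built on, so each is implemented explicitly and cross-checked in the test
suite against an independent route (pair enumeration, statsmodels,
scikit-learn, published studentized-range quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .errors import DataError

__all__ = [
    "MKResult", "mann_kendall",
    "LogitFit", "fit_logit_trend", "odds_summary",
    "GroupSummary", "anova_tukey_letters",
    "PCAResult", "pca_3var",
]


# ----------------------------------------------------------------------
# Mann-Kendall trend test
# ----------------------------------------------------------------------

@dataclass
class MKResult:
    """Mann-Kendall test outcome.

    ``s`` is the pair-sign sum over all ordered pairs, ``var_s`` its
    tie-corrected variance, ``tau`` the tie-corrected rank correlation,
    ``z`` the continuity-corrected normal score and ``p`` the two-sided
    normal p-value.  ``reason`` is set (and the statistics are NaN) when
    the series is too short to test.
    """

    s: float
    var_s: float
    tau: float
    z: float
    p: float
    n: int
    reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.reason is None


def mann_kendall(series) -> MKResult:
    """Mann-Kendall test for a monotonic trend, missing values skipped.

    S = sum over i<j of sign(x_j - x_i);
    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups;
    tau = S / sqrt(D (D - T)) with D = n(n-1)/2 and T = sum_t t(t-1)/2
    (the time axis is assumed tie-free);
    z applies the +/-1 continuity correction; p is two-sided normal.

    An all-equal series degenerates to tau = 0, p = 1.
    """
    x = np.asarray(pd.Series(series).dropna(), dtype=float)
    n = x.size
    if n < 3:
        return MKResult(np.nan, np.nan, np.nan, np.nan, np.nan, n,
                        reason=f"needs >=3 non-missing values, got {n}")

    sign = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(sign, 1).sum())

    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1].astype(float)
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))) / 18.0

    d = n * (n - 1) / 2.0
    ties = float(np.sum(t * (t - 1) / 2.0))
    denom = np.sqrt(d * (d - ties))
    if denom == 0:  # every value identical
        return MKResult(s, var_s, 0.0, 0.0, 1.0, n)
    tau = s / denom

    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MKResult(s, var_s, float(tau), float(z), p, n)


# ----------------------------------------------------------------------
# Logistic trend fit (two-parameter IRLS with separation flagging)
# ----------------------------------------------------------------------

@dataclass
class LogitFit:
    """Intercept/slope logistic fit of a binary response on time.

    The slope is log-odds per original time unit.  ``intercept`` is on
    the original time scale; internally the fit centres time at
    ``t_center`` for conditioning, which changes only the intercept.
    Separation (a response pattern perfectly ordered by time, under
    which the MLE diverges) is flagged and the last iterate reported
    rather than raising.
    """

    intercept: float
    slope: float
    se_slope: float
    z_wald: float
    p_wald: float
    converged: bool
    separation: bool
    t_center: float
    n: int
    n_iter: int
    se_intercept: float = np.nan

    @property
    def intercept_centered(self) -> float:
        return self.intercept + self.slope * self.t_center

    def predict(self, t) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(t, dtype=float))

    def summary_row(self) -> dict:
        """Log-odds estimate / SE / Z / p, the conventional report layout."""
        return {
            "log_odds_estimate": self.slope,
            "std_error": self.se_slope,
            "z_score": self.z_wald,
            "p_value": self.p_wald,
            "converged": self.converged,
            "separation": self.separation,
        }


# flag-and-report thresholds for a diverging MLE at the iteration cap
_SEP_SLOPE = 15.0
_SEP_SE = 100.0


def fit_logit_trend(t, y, max_iter: int = 25, tol: float = 1e-8) -> LogitFit:
    """Maximum-likelihood logistic regression of binary ``y`` on time ``t``.

    Newton/IRLS on centred time; convergence when the coefficient step
    drops below ``tol``.  With complete or quasi-complete separation the
    likelihood is monotone and the iterates diverge: the fit is flagged
    (``separation=True``) and the capped iterate returned, mirroring how
    standard GLM software prints a huge estimate and standard error
    rather than failing.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 2 or np.unique(t).size < 2:
        raise DataError("logistic trend needs >=2 distinct time values")
    if not np.all((y == 0) | (y == 1)):
        raise DataError("response must be binary 0/1")

    tc = float(t.mean())
    x = t - tc
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    # constant response: the intercept diverges; flag as degenerate separation
    degenerate = y.min() == y.max()

    converged = False
    cov = np.full((2, 2), np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX)

    se_i, se_s = np.sqrt(np.abs(np.diag(cov)))
    slope = float(beta[1])
    separation = bool(degenerate or (not converged and
                                     (abs(slope) > _SEP_SLOPE or se_s > _SEP_SE)))
    z = slope / se_s if se_s > 0 else np.nan
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return LogitFit(
        intercept=float(beta[0] - slope * tc), slope=slope,
        se_slope=float(se_s), z_wald=float(z), p_wald=p,
        converged=converged and not degenerate, separation=separation,
        t_center=tc, n=int(t.size), n_iter=it, se_intercept=float(se_i),
    )


def odds_summary(fit: LogitFit, t0: float, t1: float) -> dict:
    """Total odds-ratio and probability change of the event over [t0, t1].

    ``odds_ratio_total`` = exp(slope * (t1 - t0)); ``delta_probability``
    is the fitted event probability at t1 minus at t0.  A separation
    flag on the fit propagates to the summary.
    """
    if not t1 > t0:
        raise DataError(f"need t1 > t0, got [{t0}, {t1}]")
    p0, p1 = fit.predict([t0, t1])
    return {
        "odds_ratio_total": float(np.exp(fit.slope * (t1 - t0))),
        "delta_probability": float(p1 - p0),
        "p0": float(p0),
        "p1": float(p1),
        "separation": fit.separation,
    }


# ----------------------------------------------------------------------
# One-way ANOVA + Tukey HSD + compact letter display
# ----------------------------------------------------------------------

@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    min: float
    max: float
    q3: float
    letters: str = ""

    def as_row(self) -> dict:
        return {"group": self.name, "n": self.n, "mean": self.mean,
                "min": self.min, "max": self.max, "q3": self.q3,
                "significance": self.letters}


def _compact_letters(names: list[str], sig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``names`` must be ordered (here: descending group mean) — letters are
    assigned in that order for stable output.  Two groups share a letter
    iff their pair is NOT in ``sig``.
    """
    columns: list[set[str]] = [set(names)]
    for pair in sig:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
            # absorb columns contained in another
            columns = [c for c in columns
                       if c and not any(c < d for d in columns if d is not c)]
    # deduplicate identical columns, order by first member's rank
    uniq: list[set[str]] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    rank = {g: i for i, g in enumerate(names)}
    uniq.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for i, col in enumerate(uniq):
        for g in names:
            if g in col:
                out[g] += alphabet[i % len(alphabet)]
    return out


def anova_tukey_letters(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA with all-pairs Tukey HSD and compact letters.

    Returns ``(summaries, f_stat, p_value, pairs)`` where ``summaries``
    is a list of :class:`GroupSummary` (mean, min, max, third quartile,
    letter codes) and ``pairs`` the Tukey table.  Two groups share a
    letter iff their HSD comparison at ``alpha`` is non-significant.
    Tukey uses the studentized-range distribution with the
    Tukey-Kramer unequal-n half-sample convention.
    """
    if len(groups) < 2:
        raise DataError("need >=2 groups")
    data = {k: np.asarray(pd.Series(v).dropna(), dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise DataError(f"group {k!r} needs n>=2, got {v.size}")

    k = len(data)
    ns = {g: v.size for g, v in data.items()}
    means = {g: float(v.mean()) for g, v in data.items()}
    big_n = sum(ns.values())
    df_within = big_n - k
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in data.items())
    mse = sse / df_within
    grand = sum(v.sum() for v in data.values()) / big_n
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in data)
    if mse == 0:
        f_stat, p_value = (np.inf, 0.0) if ssb > 0 else (0.0, 1.0)
    else:
        f_stat = (ssb / (k - 1)) / mse
        p_value = float(sps.f.sf(f_stat, k - 1, df_within))

    names = sorted(data, key=lambda g: -means[g])
    sig: set[frozenset] = set()
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q_obs = np.inf if means[a] != means[b] else 0.0
            else:
                q_obs = abs(means[a] - means[b]) / se
            p_pair = float(sps.studentized_range.sf(q_obs, k, df_within))
            significant = p_pair < alpha
            if significant:
                sig.add(frozenset((a, b)))
            pairs.append({"group_a": a, "group_b": b, "q": float(q_obs),
                          "p_adj": p_pair, "significant": significant})

    letters = _compact_letters(names, sig)
    summaries = [
        GroupSummary(g, ns[g], means[g], float(data[g].min()), float(data[g].max()),
                     float(np.quantile(data[g], 0.75)), letters[g])
        for g in sorted(data)
    ]
    return summaries, float(f_stat), float(p_value), pairs


# ----------------------------------------------------------------------
# Standardized three-variable PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    """PCA of standardized columns; loadings columns are orthonormal.

    ``arrows`` are biplot arrow coordinates, loading x sqrt(eigenvalue).
    Per component the sign is fixed so the largest-|loading| entry is
    positive, making output deterministic.
    """

    variables: list[str]
    loadings: np.ndarray          # (p, p), column = component
    explained: np.ndarray         # variance fractions, non-increasing
    scores: np.ndarray            # (n, p)
    eigenvalues: np.ndarray = field(default=None)

    @property
    def arrows(self) -> np.ndarray:
        return self.loadings * np.sqrt(self.eigenvalues)[None, :]


def pca_3var(data, variables: list[str] | None = None) -> PCAResult:
    """PCA on standardized columns (typically elevation, LST, RZSM).

    Columns are centred and scaled to unit variance (ddof=1), then
    decomposed by SVD.  Rows with any missing value are dropped; at
    least 3 complete rows and positive variance in every column are
    required.
    """
    if isinstance(data, pd.DataFrame):
        variables = variables or list(data.columns)
        X = data[variables].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        variables = variables or [f"var{i}" for i in range(X.shape[1])]
    X = X[np.all(np.isfinite(X), axis=1)]
    n, p = X.shape
    if n < 3:
        raise DataError(f"PCA needs >=3 complete rows, got {n}")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(variables, sd):
        if s == 0:
            raise DataError(f"variable {name!r} has zero variance")
    Xs = (X - X.mean(axis=0)) / sd

    u, svals, vt = np.linalg.svd(Xs, full_matrices=False)
    loadings = vt.T
    eig = svals ** 2 / (n - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(p):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    scores = u * svals
    return PCAResult(variables=list(variables), loadings=loadings,
                     explained=eig / eig.sum(), scores=scores, eigenvalues=eig)
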