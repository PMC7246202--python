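"""Random-effects meta-analysis: REML between-study variance, pooled
effect with Wald confidence interval, and Cochran's Q heterogeneity test.

Model: observed effects y_i ~ Normal(theta, v_i + tau^2) with known
sampling variances v_i and between-study variance tau^2 estimated by
restricted maximum likelihood via Fisher scoring with step-halving and
truncation at zero.  Pooling uses random-effects weights
w_i = 1/(v_i + tau^2); the 95% CI is Wald (z).  Cochran's Q uses
fixed-effect weights 1/v_i and a chi-square reference with k-1 df.

Implemented from first principles (no meta-analysis package); a
brute-force restricted-likelihood grid search lives in the test suite as
the independent oracle for the Fisher-scoring estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "REMLFit",
    "reml_tau2",
    "restricted_loglik",
    "pool",
    "q_test",
    "fit",
]

Z975 = norm.ppf(0.975)
V_FLOOR = 1e-12  # weights 1/v must stay finite


@dataclass(frozen=True)
class REMLFit:
    """Result of a random-effects fit on k effects."""

    k: int
    tau2: float
    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    q: float
    q_df: int
    q_p: float
    significant: bool
    converged: bool
    iterations: int
    degenerate: bool = False  # k < 2: tau2 fixed at 0, Q undefined


def _as_arrays(effects: Sequence[Tuple[float, float]]) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("effects must be a sequence of (lnrr, v) pairs")
    y, v = arr[:, 0], arr[:, 1]
    if np.any(v < 0):
        raise ValueError("sampling variances must be non-negative")
    v = np.maximum(v, V_FLOOR)
    return y, v


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau2 for effects y with variances v."""
    s = v + tau2
    w = 1.0 / s
    sw = w.sum()
    mu = (w * y).sum() / sw
    return -0.5 * (np.log(s).sum() + math.log(sw) + (w * (y - mu) ** 2).sum())


def reml_tau2(
    effects: Sequence[Tuple[float, float]],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> Tuple[float, bool, int]:
    """REML estimate of the between-study variance tau^2.

    Fisher scoring on tau^2 with step-halving whenever a step would lower
    the restricted likelihood, truncated at zero.  Returns
    (tau2, converged, iterations); k < 2 returns (0.0, True, 0).
    """
    y, v = _as_arrays(effects)
    k = y.size
    if k < 2:
        return 0.0, True, 0

    # DerSimonian-Laird start, truncated at 0.
    w_fe = 1.0 / v
    mu_fe = (w_fe * y).sum() / w_fe.sum()
    q = (w_fe * (y - mu_fe) ** 2).sum()
    c = w_fe.sum() - (w_fe**2).sum() / w_fe.sum()
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0

    converged = False
    it = 0
    ll = restricted_loglik(tau2, y, v)
    for it in range(1, max_iter + 1):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        mu = (w * y).sum() / sw
        w2 = w * w
        resid2 = (y - mu) ** 2
        score = 0.5 * ((w2 * resid2).sum() - w.sum() + (w2.sum() / sw))
        info = 0.5 * (w2.sum() - 2.0 * (w**3).sum() / sw + (w2.sum() / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        new = max(0.0, tau2 + step)
        # Step-halving: never accept a step that lowers the restricted ll.
        new_ll = restricted_loglik(new, y, v)
        halvings = 0
        while new_ll < ll - 1e-13 and halvings < 50:
            step *= 0.5
            new = max(0.0, tau2 + step)
            new_ll = restricted_loglik(new, y, v)
            halvings += 1
        delta = new - tau2
        tau2, ll = new, new_ll
        if abs(delta) <= tol * (abs(tau2) + tol):
            converged = True
            break
        # At the boundary with an inward-pointing score, 0 is the optimum.
        if tau2 == 0.0 and score < 0:
            converged = True
            break
    return tau2, converged, it


def pool(
    effects: Sequence[Tuple[float, float]],
    tau2: float,
    weights: str = "inverse_variance",
) -> Tuple[float, float, float, float]:
    """Pooled estimate with 95% Wald CI under random-effects weights.

    ``weights='equal'`` gives the unweighted companion analysis (all
    w_i = 1; the SE is then the naive SE of the mean of y under the
    model variances).
    """
    y, v = _as_arrays(effects)
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if weights == "inverse_variance":
        w = 1.0 / (v + tau2)
        pooled = (w * y).sum() / w.sum()
        se = 1.0 / math.sqrt(w.sum())
    elif weights == "equal":
        k = y.size
        pooled = y.mean()
        se = math.sqrt((v + tau2).sum()) / k
    else:
        raise ValueError(f"unknown weights {weights!r}")
    return pooled, se, pooled - Z975 * se, pooled + Z975 * se


def q_test(effects: Sequence[Tuple[float, float]]) -> Tuple[float, int, float]:
    """Cochran's Q heterogeneity test with fixed-effect weights.

    Returns (Q, df, p).  A single effect gives Q=0, df=0 and p reported
    as 1 (test undefined).
    """
    y, v = _as_arrays(effects)
    k = y.size
    if k < 2:
        return 0.0, 0, 1.0
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    q = float((w * (y - ybar) ** 2).sum())
    df = k - 1
    return q, df, float(chi2.sf(q, df))


def fit(
    effects: Sequence[Tuple[float, float]],
    weights: str = "inverse_variance",
) -> REMLFit:
    """Full random-effects fit: REML tau^2, pooled CI, Q test, verdict."""
    if len(effects) == 0:
        raise ValueError("cannot fit an empty effect set")
    y, v = _as_arrays(effects)
    k = y.size
    tau2, converged, iterations = reml_tau2(effects)
    pooled, se, lo, hi = pool(effects, tau2, weights=weights)
    q, df, p = q_test(effects)
    return REMLFit(
        k=k,
        tau2=float(tau2),
        pooled=float(pooled),
        se_pooled=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        q=q,
        q_df=df,
        q_p=p,
        significant=bool(lo > 0.0 or hi < 0.0),
        converged=converged,
        iterations=iterations,
        degenerate=(k < 2),
    )
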