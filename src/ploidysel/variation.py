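"""Standing-variation and cytometry summaries.

The coefficient of variation (CV = 100 * sd / mean) is the scale-free
measure of standing phenotypic variation tracked across selection
generations.  Its confidence interval follows from the exact noncentral-t
pivot: for a Normal sample of size n,

    T = sqrt(n) * mean / sd   ~   noncentral t(n - 1, ncp = sqrt(n) / cv)

so the interval is obtained by inverting the noncentral-t CDF in its
noncentrality parameter.  The interval is asymmetric (wider above) for
finite n, matching the behaviour of the MBESS ``ci.cv`` estimator.

Relative 2C DNA content converts flow-cytometry peak positions to picograms
against a co-chopped internal standard of known genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .errors import EstimationError

#: 2C DNA content of the Epilobium hirsutum internal standard, picograms.
STANDARD_2C_PG = 0.87


@dataclass(frozen=True)
class CvEstimate:
    cv: float
    n: int
    lower_cl: float
    upper_cl: float
    level: float


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent (n-1 denominator SD); requires a positive mean
    and at least two observations."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise EstimationError("CV needs at least two observations")
    mean = float(arr.mean())
    if mean <= 0:
        raise EstimationError("CV requires a positive mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


def _noncentrality_from_cdf(t_obs, df, prob):
    """Solve nct_cdf(t_obs; df, ncp) = prob for the noncentrality parameter.

    Bracketed bisection with expanding brackets (the CDF is strictly
    decreasing in the noncentrality parameter); vectorized over ``t_obs``
    and ``prob``.  Deterministic, tolerance 1e-8.
    """
    t = np.atleast_1d(np.asarray(t_obs, dtype=float))
    p = np.broadcast_to(np.asarray(prob, dtype=float), t.shape).copy()
    step = 2.0 + 4.0 * np.sqrt(1.0 + t**2 / (2.0 * (df + 1.0)))
    lo = t - step
    hi = t + step
    for _ in range(200):  # expand until the root is bracketed
        too_high = special.nctdtr(df, lo, t) < p  # need smaller ncp
        too_low = special.nctdtr(df, hi, t) > p  # need larger ncp
        if not (too_high.any() or too_low.any()):
            break
        lo = np.where(too_high, lo - step, lo)
        hi = np.where(too_low, hi + step, hi)
    else:  # pragma: no cover - pathological inputs
        raise EstimationError("noncentrality bracketing failed to converge")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        high_side = special.nctdtr(df, mid, t) > p
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
        if np.max(hi - lo) < 1e-8:
            break
    out = 0.5 * (lo + hi)
    return out if np.ndim(t_obs) else float(out[0])


def cv_confidence_interval(
    cv: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Noncentral-t confidence interval for a CV given in percent.

    With t_obs = sqrt(n) / (cv/100), the bounds are 100*sqrt(n)/ncp_U and
    100*sqrt(n)/ncp_L, where t_obs sits at the upper and lower tail
    probabilities of the noncentral t with n-1 degrees of freedom.  An
    upper noncentrality at or below zero yields an infinite upper bound.
    """
    if cv <= 0:
        raise EstimationError("cv must be positive")
    if n < 2:
        raise EstimationError("need n >= 2")
    if not 0.0 < level < 1.0:
        raise EstimationError("level must be in (0, 1)")
    lower, upper = cv_confidence_interval_vec(
        np.array([cv]), np.array([n]), level
    )
    return float(lower[0]), float(upper[0])


def cv_confidence_interval_vec(cv, n, level: float = 0.95):
    """Vectorized form of :func:`cv_confidence_interval` for arrays of CVs
    (percent) and sample sizes."""
    cv = np.asarray(cv, dtype=float)
    n = np.asarray(n, dtype=float)
    t_obs = np.sqrt(n) / (cv / 100.0)
    alpha = 1.0 - level
    # the CDF is decreasing in ncp: the upper-tail probability gives the
    # smaller root (ncp_L), the lower-tail the larger (ncp_U)
    if np.unique(n).size == 1:
        df = float(n.flat[0]) - 1.0
        ncp_l = _noncentrality_from_cdf(t_obs, df, 1.0 - alpha / 2.0)
        ncp_u = _noncentrality_from_cdf(t_obs, df, alpha / 2.0)
    else:
        ncp_l = np.empty_like(t_obs)
        ncp_u = np.empty_like(t_obs)
        for i, (ti, ni) in enumerate(zip(np.ravel(t_obs), np.ravel(n))):
            ncp_l.flat[i] = _noncentrality_from_cdf(ti, ni - 1.0, 1.0 - alpha / 2.0)
            ncp_u.flat[i] = _noncentrality_from_cdf(ti, ni - 1.0, alpha / 2.0)
    lower = 100.0 * np.sqrt(n) / ncp_u
    upper = np.where(ncp_l > 0, 100.0 * np.sqrt(n) / np.maximum(ncp_l, 1e-12), np.inf)
    return np.atleast_1d(lower), np.atleast_1d(upper)


def cv_estimate(values: Sequence[float], level: float = 0.95) -> CvEstimate:
    cv = coefficient_of_variation(values)
    n = int(np.asarray(values).size)
    lo, hi = cv_confidence_interval(cv, n, level)
    return CvEstimate(cv=cv, n=n, lower_cl=lo, upper_cl=hi, level=level)


def cv_table(df, level: float = 0.95):
    """Per-line, per-generation CV table (fertile plants only) from a
    phenotype table with columns line, generation, fertile,
    phenotype_days."""
    import pandas as pd

    rows = []
    fertile = df[df["fertile"].astype(bool)]
    for (line, gen), grp in sorted(
        fertile.groupby(["line", "generation"], sort=False).groups.items()
    ):
        vals = fertile.loc[grp, "phenotype_days"].to_numpy()
        if len(vals) < 2:
            continue
        est = cv_estimate(vals, level)
        rows.append(
            {
                "line": line,
                "generation": int(gen),
                "cv": round(est.cv, 4),
                "lcl": round(est.lower_cl, 4),
                "ucl": round(est.upper_cl, 4),
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def dna_content_2c(
    sample_peak: float,
    standard_peak: float,
    standard_2c: float = STANDARD_2C_PG,
) -> float:
    """2C DNA content (pg) from fluorescence peak positions: the
    sample/standard peak ratio times the standard's known 2C content.
    Scale-invariant in detector units."""
    if sample_peak <= 0 or standard_peak <= 0:
        raise EstimationError("peak positions must be positive")
    return sample_peak / standard_peak * standard_2c
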