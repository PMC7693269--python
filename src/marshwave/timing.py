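"""Site-level timing inference across latitude.

Covers the estimators and tests that connect annual-cycle event timing to
latitude:

* random-intercept linear mixed model (individual as random effect, site
  as fixed effect) giving site marginal-mean event dates that account for
  individuals tracked in more than one year; variance components by
  restricted maximum likelihood, profiled down to a bounded scalar search
  over the variance ratio;
* ordinary least-squares regression of marginal means on latitude, and a
  pooled-interaction test of slope homogeneity between two event series;
* arrival estimation by tail alignment (shifting a reference sample's
  mean-minus-minimum offset onto the earliest date reported by a historic
  study) and by the cumulative-2% rule on observation-frequency records;
* maximally selected statistics: the largest standardized two-group mean
  difference over all admissible latitude cutpoints, with a seeded
  permutation p value (exact at small n, testable against brute force).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class CutpointResult:
    """Maximally selected statistic over latitude cutpoints."""

    cutpoint: float
    t_max: float
    p_perm: float
    mean_below: float
    mean_above: float
    n_below: int
    n_above: int


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

def fit_random_intercept(records: pd.DataFrame, tol: float = 1e-10):
    """Site marginal-mean event dates from a random-intercept mixed model.

    ``records`` needs columns ``individual_id, site, doy``.  The model is
    ``doy = site effect + individual random intercept + residual`` with
    variance components estimated by REML, profiled over the ratio
    ``lambda = sigma_u^2 / sigma_e^2`` and optimized by bounded scalar
    search on the log scale.  Site cell means are the marginal means; SEs
    come from the fixed-effect covariance.

    Returns ``(estimates, varcomp)`` where ``estimates`` has columns
    ``site, marginal_mean, se, n``.  With a single site a plain mean and
    SE are returned with a warning.
    """
    df = records.reset_index(drop=True)
    y = df["doy"].to_numpy(float)
    n = len(df)
    sites = list(pd.unique(df["site"]))
    if len(sites) == 1:
        warnings.warn("single site: returning the plain mean")
        se = float(y.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        est = pd.DataFrame({"site": sites, "marginal_mean": [float(y.mean())], "se": [se], "n": [n]})
        return est, {"sigma_u": np.nan, "sigma_e": float(y.std(ddof=1)) if n > 1 else np.nan,
                     "lambda": np.nan}
    if n < 3:
        raise ValueError("need at least 3 records")

    X = (df["site"].to_numpy()[:, None] == np.array(sites)[None, :]).astype(float)
    indivs = list(pd.unique(df["individual_id"]))
    Z = (df["individual_id"].to_numpy()[:, None] == np.array(indivs)[None, :]).astype(float)
    p = X.shape[1]

    def reml_pieces(lam):
        V = np.eye(n) + lam * (Z @ Z.T)
        L = np.linalg.cholesky(V)
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        q = float(r @ np.linalg.solve(V, r))
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        return beta, XtViX, q, logdet_V + logdet_XtViX + (n - p) * np.log(q)

    def objective(log_lam):
        return reml_pieces(np.exp(log_lam))[3]

    res = optimize.minimize_scalar(objective, bounds=(-25.0, 12.0), method="bounded",
                                   options={"xatol": tol})
    lam = float(np.exp(res.x))
    # boundary case: variance ratio indistinguishable from zero
    if objective(-25.0) <= res.fun:
        lam = 0.0
    beta, XtViX, q, _ = reml_pieces(lam)
    sigma_e2 = q / (n - p)
    cov_beta = sigma_e2 * np.linalg.inv(XtViX)
    counts = df.groupby("site", sort=False)["doy"].size().reindex(sites).to_numpy()
    est = pd.DataFrame({"site": sites, "marginal_mean": beta,
                        "se": np.sqrt(np.diag(cov_beta)), "n": counts})
    return est, {"sigma_u": float(np.sqrt(lam * sigma_e2)), "sigma_e": float(np.sqrt(sigma_e2)),
                 "lambda": lam}


# ---------------------------------------------------------------------------
# latitude regressions
# ---------------------------------------------------------------------------

def latitude_regression(estimates: pd.DataFrame) -> dict:
    """OLS of site marginal mean on latitude: slope (days/deg), intercept, R^2, p."""
    if len(estimates) < 3:
        raise ValueError("need at least 3 sites")
    res = stats.linregress(estimates["latitude"].to_numpy(float),
                           estimates["marginal_mean"].to_numpy(float))
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue), "n": len(estimates)}


def slope_homogeneity(series_a: pd.DataFrame, series_b: pd.DataFrame) -> dict:
    """Test whether two timing-vs-latitude series share a slope.

    Pooled regression with category, latitude and category x latitude
    terms; returns the interaction coefficient and its t-test p value.
    """
    if len(series_a) < 3 or len(series_b) < 3:
        raise ValueError("both series need at least 3 points")
    lat = np.concatenate([series_a["latitude"].to_numpy(float), series_b["latitude"].to_numpy(float)])
    yy = np.concatenate([series_a["marginal_mean"].to_numpy(float),
                         series_b["marginal_mean"].to_numpy(float)])
    cat = np.concatenate([np.zeros(len(series_a)), np.ones(len(series_b))])
    X = np.column_stack([np.ones_like(lat), lat, cat, cat * lat])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design for slope comparison")
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[3, 3]))
    t = float(beta[3]) / se if se > 0 else np.inf * np.sign(beta[3])
    pval = 2.0 * stats.t.sf(abs(t), df=n - p)
    return {"interaction": float(beta[3]), "se": se, "t": t, "p": float(pval)}


# ---------------------------------------------------------------------------
# arrival estimators
# ---------------------------------------------------------------------------

def tail_align_estimate(reference, earliest_new: float) -> dict:
    """Mean-date estimate by aligning the reference sample's left tail.

    The left tail is defined as the reference minimum: the estimate is
    ``earliest_new + (mean(reference) - min(reference))``.  Reports the
    reference span as a diagnostic.
    """
    ref = np.asarray(reference, dtype=float)
    if len(ref) < 3:
        raise ValueError("reference sample must have at least 3 dates")
    offset = float(ref.mean() - ref.min())
    return {"estimate": float(earliest_new) + offset, "offset": offset,
            "reference_span": float(ref.max() - ref.min()), "n_reference": int(len(ref))}


def arrival_from_observations(counts: pd.DataFrame, fraction: float = 0.02,
                              season_window: tuple = (1, 181)) -> pd.DataFrame:
    """Arrival day per latitude bin by the cumulative-percentage rule.

    ``counts`` needs columns ``doy, n_reporting`` plus optional ``year``
    and ``bin_latitude``.  Per bin and year, the arrival day is the first
    day-of-year at which the cumulative count reaches ``fraction`` of the
    within-window seasonal total (>=, first qualifying day); yearly
    estimates are averaged and their SE across years reported.
    """
    df = counts.copy()
    if "bin_latitude" not in df.columns:
        df["bin_latitude"] = np.nan
    if "year" not in df.columns:
        df["year"] = 1
    lo, hi = season_window
    df = df[(df["doy"] >= lo) & (df["doy"] <= hi)]
    rows = []
    for lat, grp in df.groupby("bin_latitude", dropna=False):
        yearly = []
        for _yr, g in grp.groupby("year"):
            g = g.sort_values("doy")
            total = g["n_reporting"].sum()
            if total <= 0:
                raise ValueError("zero seasonal total of observations in the window")
            cum = g["n_reporting"].cumsum() / total
            yearly.append(int(g.loc[(cum >= fraction).idxmax(), "doy"]))
        yearly = np.array(yearly, dtype=float)
        se = float(yearly.std(ddof=1) / np.sqrt(len(yearly))) if len(yearly) > 1 else np.nan
        rows.append({"bin_latitude": lat, "arrival_doy": float(yearly.mean()), "se": se,
                     "n_years": len(yearly)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# maximally selected statistics
# ---------------------------------------------------------------------------

def _tmax(x_sorted_cumsum, y_stats, cut_sizes):
    """Standardized linear statistic at each candidate left-group size."""
    n, ybar, ssy = y_stats
    S = x_sorted_cumsum[cut_sizes - 1]
    E = cut_sizes * ybar
    V = cut_sizes * (n - cut_sizes) / (n * (n - 1.0)) * ssy
    return (S - E) / np.sqrt(V)


def maxstat_cutpoint(x, y, min_prop: float = 0.1, n_perm: int = 10000, seed=None) -> CutpointResult:
    """Maximally selected standardized statistic over cutpoints of ``x``.

    Candidate cutpoints are midpoints between sorted unique ``x`` values
    leaving at least ``min_prop`` of the points on each side.  At each
    cutpoint the standardized two-group statistic ``T = (S - E)/sqrt(V)``
    is computed for the left-group sum ``S`` under the permutation
    distribution; ``T_max`` is the maximum absolute statistic and the
    cutpoint its argmax (ties broken toward smaller ``x``).  The p value
    is the plus-one-corrected proportion of ``n_perm`` permutations of
    ``y`` whose ``T_max`` reaches the observed one (NaN when
    ``n_perm == 0``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 points")
    if not 0.0 < min_prop < 0.5:
        raise ValueError("min_prop must be in (0, 0.5)")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ybar = ys.mean()
    ssy = float(((ys - ybar) ** 2).sum())
    # left-group sizes at which x strictly increases, within the proportion limits
    boundary = np.flatnonzero(np.diff(xs) > 0) + 1
    sizes = boundary[(boundary >= min_prop * n) & (n - boundary >= min_prop * n)]
    if len(sizes) == 0:
        raise ValueError("no admissible cutpoints for this min_prop")
    if ssy == 0:
        k = sizes[0]
        return CutpointResult(cutpoint=float((xs[k - 1] + xs[k]) / 2.0), t_max=0.0, p_perm=1.0,
                              mean_below=float(ybar), mean_above=float(ybar),
                              n_below=int(k), n_above=int(n - k))
    stats_obs = np.abs(_tmax(np.cumsum(ys), (n, ybar, ssy), sizes))
    best = int(np.argmax(stats_obs))  # first maximum -> smaller x on ties
    t_max = float(stats_obs[best])
    k = int(sizes[best])
    cut = float((xs[k - 1] + xs[k]) / 2.0)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(ys, (n_perm, n)).copy(), axis=1)
        cums = np.cumsum(perms, axis=1)
        S = cums[:, sizes - 1]
        E = sizes * ybar
        V = sizes * (n - sizes) / (n * (n - 1.0)) * ssy
        t_perm = np.max(np.abs((S - E) / np.sqrt(V)), axis=1)
        p = (1.0 + float(np.sum(t_perm >= t_max - 1e-12))) / (1.0 + n_perm)
    else:
        p = np.nan
    return CutpointResult(cutpoint=cut, t_max=t_max, p_perm=p,
                          mean_below=float(ys[:k].mean()), mean_above=float(ys[k:].mean()),
                          n_below=k, n_above=n - k)
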