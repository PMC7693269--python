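"""Green-wave model of seasonal salt-marsh biomass across latitude.

Multi-study seasonal biomass measurements are standardized to a
*phenological stage* -- the fraction of the within-study seasonal maximum
of mean standing biomass ("percent of total seasonal biomass") -- which
makes studies with very different absolute productivity comparable.

The stage is then modelled on the 0-1 fraction scale with an identity
link as

    stage = b0 + b_date*doy + b_lat*lat + b_datelat*doy*lat

fitted as an inverse-variance weighted generalized estimating equation:
iterated generalized least squares under a block-diagonal AR(1) working
correlation per study (repeated measures ordered by visit), alternating
with moment re-estimation of the working correlation rho from lag-1
standardized residuals.  Standard errors are robust (sandwich) with the
usual small-sample cluster correction; model-based SEs are available by
flag.  With rho = 0 and equal weights the fit reduces exactly to
(weighted) least squares.

Inverting the fitted linear predictor gives the date a target stage is
reached at a given latitude, the analogue of "the date when biomass
accumulation has reached 29.5%".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COEF_NAMES = ("intercept", "date", "latitude", "date_latitude")


class ConvergenceError(RuntimeError):
    """GEE failed to converge; carries the last iterate in ``.model``."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model


@dataclass
class GreenWaveModel:
    """Fitted date x latitude stage model (identity link, fraction scale)."""

    beta0: float
    beta_date: float
    beta_lat: float
    beta_datelat: float
    rho: float
    coef_se: np.ndarray
    cov: np.ndarray
    n_obs: int
    n_studies: int
    converged: bool = True
    n_iter: int = 0
    model_se: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_date, self.beta_lat, self.beta_datelat])

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(_COEF_NAMES, self.beta.tolist())),
            "robust_se": dict(zip(_COEF_NAMES, np.asarray(self.coef_se).tolist())),
            "rho": self.rho,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
            "converged": self.converged,
        }

    def table(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, chi-square, p) on the stage scale."""
        se = np.asarray(self.coef_se)
        chi2 = (self.beta / se) ** 2
        p = stats.chi2.sf(chi2, df=1)
        return pd.DataFrame({"term": _COEF_NAMES, "estimate": self.beta, "se": se,
                             "chi_square": chi2, "p": p})


def standardize_biomass(observations: pd.DataFrame) -> pd.DataFrame:
    """Convert biomass means/SEs to stage fractions of the within-study seasonal maximum.

    Requires columns ``study_id, latitude, doy, biomass_mean, biomass_se, n``
    (optionally ``year``; study-years are standardized separately when
    present).  Adds ``stage, stage_se, weight`` with
    ``weight = 1 / stage_se**2``.  Stages above 1 under noise are retained
    unclipped to avoid bias.
    """
    df = observations.copy()
    keys = ["study_id", "year"] if "year" in df.columns else ["study_id"]
    out = []
    for _key, grp in df.groupby(keys):
        if len(grp) < 2:
            raise ValueError("each study-year needs at least 2 observations")
        total = grp["biomass_mean"].max()
        if total <= 0:
            raise ValueError("zero seasonal total in a study-year")
        if (grp["biomass_se"] <= 0).any():
            raise ValueError("biomass_se must be positive for inverse-variance weighting")
        g = grp.copy()
        g["stage"] = g["biomass_mean"] / total
        g["stage_se"] = g["biomass_se"] / total
        g["weight"] = 1.0 / g["stage_se"] ** 2
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def fit_greenwave(standardized: pd.DataFrame, max_iter: int = 50, tol: float = 1e-8,
                  small_sample_correction: bool = True, working: str = "ar1") -> GreenWaveModel:
    """Fit the date x latitude stage model by iterated GLS with an AR(1) working correlation.

    ``standardized`` needs columns ``study_id, latitude, doy, stage,
    stage_se`` (from :func:`standardize_biomass`).  Within-study repeated
    measures are ordered by visit (doy order); observation-level variances
    are ``stage_se**2`` (inverse-variance weighting).  Iterates weighted
    GLS given the working covariance and moment re-estimation of rho from
    lag-1 standardized residuals until the largest coefficient change is
    below ``tol`` (or raises :class:`ConvergenceError` carrying the last
    iterate).

    ``working`` selects the working correlation: ``"ar1"`` (default) or
    ``"independence"`` (rho held at 0, i.e. weighted least squares with
    cluster-robust errors) -- the defensive choice when the linear mean
    model is only an approximation, since a moment-estimated rho then
    absorbs systematic lack of fit and can destabilize the coefficients.
    """
    if working not in ("ar1", "independence"):
        raise ValueError("working must be 'ar1' or 'independence'")
    df = standardized.sort_values(["study_id", "doy"]).reset_index(drop=True)
    n = len(df)
    if df["study_id"].nunique() < 2 or n < 6:
        raise ValueError("need at least 2 studies and 6 observations")
    X = np.column_stack([
        np.ones(n), df["doy"].to_numpy(float), df["latitude"].to_numpy(float),
        df["doy"].to_numpy(float) * df["latitude"].to_numpy(float),
    ])
    y = df["stage"].to_numpy(float)
    sd = df["stage_se"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        detail = "single latitude makes latitude and interaction collinear" \
            if df["latitude"].nunique() == 1 else "design matrix is rank deficient"
        raise ValueError(f"singular design: {detail}")

    blocks = [np.flatnonzero(df["study_id"].to_numpy() == s) for s in df["study_id"].unique()]
    p = X.shape[1]

    def gls(rho):
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        for idx in blocks:
            D = sd[idx]
            V = _ar1_corr(len(idx), rho) * np.outer(D, D)
            Vi = np.linalg.inv(V)
            XtViX += X[idx].T @ Vi @ X[idx]
            XtViy += X[idx].T @ Vi @ y[idx]
        return np.linalg.solve(XtViX, XtViy), XtViX

    def moment_rho(beta):
        e = (y - X @ beta) / sd
        phi = float(e @ e) / (n - p)
        num, pairs = 0.0, 0
        for idx in blocks:
            es = e[idx]
            num += float(es[:-1] @ es[1:])
            pairs += len(idx) - 1
        den = (pairs - p) * phi
        if den <= 0:
            return 0.0
        return float(np.clip(num / den, -0.99, 0.99))

    beta, XtViX = gls(0.0)
    rho = 0.0
    converged = False
    for it in range(1, max_iter + 1):
        rho = moment_rho(beta) if working == "ar1" else 0.0
        beta_new, XtViX = gls(rho)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    # sandwich covariance; with few clusters the plain sandwich badly
    # under-covers, so the default applies the Mancl-DeRouen bias correction
    # (per-cluster residuals inflated by (I - H_i)^-1)
    M = XtViX
    Minv = np.linalg.inv(M)
    G = len(blocks)
    B = np.zeros((p, p))
    for idx in blocks:
        D = sd[idx]
        V = _ar1_corr(len(idx), rho) * np.outer(D, D)
        Vi = np.linalg.inv(V)
        r = y[idx] - X[idx] @ beta
        if small_sample_correction:
            H = X[idx] @ Minv @ X[idx].T @ Vi
            r = np.linalg.solve(np.eye(len(idx)) - H, r)
        g = X[idx].T @ Vi @ r
        B += np.outer(g, g)
    cov = Minv @ B @ Minv
    model = GreenWaveModel(
        beta0=float(beta[0]), beta_date=float(beta[1]), beta_lat=float(beta[2]),
        beta_datelat=float(beta[3]), rho=rho, coef_se=np.sqrt(np.diag(cov)), cov=cov,
        n_obs=n, n_studies=G, converged=converged, n_iter=it,
        model_se=np.sqrt(np.diag(Minv)),
    )
    if not converged:
        raise ConvergenceError(f"GEE did not converge in {max_iter} iterations", model=model)
    return model


def predict_stage(model: GreenWaveModel, doy, latitude):
    """Predicted stage fraction at (doy, latitude) on the identity-link linear predictor."""
    d = np.asarray(doy, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    out = model.beta0 + model.beta_date * d + model.beta_lat * lat + model.beta_datelat * d * lat
    return float(out) if out.ndim == 0 else out


def stage_date(model: GreenWaveModel, target_stage: float, latitude: float) -> float:
    """Closed-form day-of-year at which the model reaches ``target_stage`` at ``latitude``."""
    denom = model.beta_date + model.beta_datelat * latitude
    if abs(denom) < 1e-12:
        raise ValueError("zero date-slope at this latitude; stage date undefined")
    return (target_stage - model.beta0 - model.beta_lat * latitude) / denom


def stage_at_events(model: GreenWaveModel, events: pd.DataFrame):
    """Predicted stage at each individual's nest date, per-site means, homogeneity test.

    ``events`` needs columns ``individual_id, site, latitude, nest_doy``;
    rows with missing nest dates are skipped (logged).  Returns
    ``(per_individual, per_site, test)`` where ``test`` is a
    Kruskal-Wallis rank test of stage homogeneity across sites.
    """
    df = events.copy()
    missing = df["nest_doy"].isna()
    if missing.any():
        logger.info("skipping %d event rows with missing nest dates", int(missing.sum()))
        df = df[~missing]
    if df.empty:
        raise ValueError("no events with nest dates")
    df = df.copy()
    df["predicted_stage"] = predict_stage(model, df["nest_doy"].to_numpy(float),
                                          df["latitude"].to_numpy(float))
    per_site = df.groupby("site", sort=False).agg(
        latitude=("latitude", "mean"), mean_stage=("predicted_stage", "mean"),
        n=("predicted_stage", "size"),
    ).reset_index()
    groups = [g["predicted_stage"].to_numpy() for _s, g in df.groupby("site", sort=False)]
    if len(groups) < 2 or np.ptp(df["predicted_stage"].to_numpy()) == 0:
        test = {"statistic": 0.0, "df": max(len(groups) - 1, 0), "p": 1.0}
    else:
        stat, pval = stats.kruskal(*groups)
        test = {"statistic": float(stat), "df": len(groups) - 1, "p": float(pval)}
    return df, per_site, test
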