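"""Group-level statistics.

Covers the cohort-level analyses: auditory covariate derivation
(better-ear pure-tone average, weekly hearing-aid use), linear
mixed-effects modeling of the entrainment power envelope (group ×
time with a per-subject random intercept), whole-brain partial
correlation mapping with a cluster-extent threshold, peak–behavior
correlations, and demographic group comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .forward import SourceGrid

__all__ = [
    "LMEFit",
    "CorrelationCluster",
    "CorrelationMapResult",
    "derive_auditory_covariates",
    "fit_entrainment_lme",
    "partial_correlation",
    "whole_brain_partial_correlation",
    "peak_behavior_correlation",
    "pooled_t_from_summary",
    "chi_square_independence",
    "demographic_comparison",
]

logger = logging.getLogger(__name__)

#: Audiogram octave frequencies entering the pure-tone average, Hz.
PTA_FREQS = (500, 1000, 2000, 4000)


def derive_auditory_covariates(thresholds_left, thresholds_right,
                               weekday_hours: float, weekend_hours: float
                               ) -> tuple[float, float]:
    """Better-ear pure-tone average (dB HL) and weekly aid use (h/week).

    The PTA per ear is the mean of the four octave thresholds
    (500/1000/2000/4000 Hz); BEPTA is the lower of the two ears.
    Weekly use is 5 × weekday + 2 × weekend daily hours.  Missing
    thresholds raise — no imputation.
    """
    out_ears = []
    for thr in (thresholds_left, thresholds_right):
        thr = np.asarray(thr, dtype=float)
        if thr.shape != (len(PTA_FREQS),) or not np.all(np.isfinite(thr)):
            raise ValueError("each ear needs 4 finite octave thresholds")
        out_ears.append(float(thr.mean()))
    for h in (weekday_hours, weekend_hours):
        if not 0 <= h <= 24:
            raise ValueError("daily hours must be within [0, 24]")
    bepta = min(out_ears)
    weekly = 5.0 * weekday_hours + 2.0 * weekend_hours
    return bepta, weekly


@dataclass
class LMEFit:
    """Fixed effects of the group × time mixed model."""

    params: pd.Series                # intercept, group, time, group×time
    bse: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    residual_var: float
    n_obs: int
    converged: bool
    method: str                      # "reml", "ml", or "ols"

    @property
    def interaction(self) -> float:
        return float(self.params["group:time_ms"])


def fit_entrainment_lme(table: pd.DataFrame) -> LMEFit:
    """Fit relative_power ~ group + time + group×time, random intercept.

    Time enters as continuous bin-center milliseconds; group is coded
    CHH = 1, CNH = 0 (so a steeper hard-of-hearing slope is a positive
    interaction).  Restricted maximum likelihood, with an ML refit and
    finally pooled OLS as logged fallbacks on convergence failure.
    """
    import statsmodels.api as sm

    groups = set(table["group"])
    if not groups <= {"CNH", "CHH"}:
        raise ValueError(f"unknown group labels: {groups}")
    per_group = table.groupby("group")["subject_id"].nunique()
    if len(per_group) < 2 or per_group.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    g = (table["group"] == "CHH").to_numpy(dtype=float)
    t = table["time_ms"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table)), g, t, g * t])
    y = table["relative_power"].to_numpy(dtype=float)
    names = ["intercept", "group", "time_ms", "group:time_ms"]

    def _pack(vals):
        return pd.Series(np.asarray(vals)[:4], index=names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, reml in (("reml", True), ("ml", False)):
            try:
                res = sm.MixedLM(y, X, table["subject_id"].to_numpy()
                                 ).fit(reml=reml)
            except Exception:
                continue
            if res.converged:
                if method != "reml":
                    logger.warning("REML did not converge; used %s", method)
                return LMEFit(_pack(res.params), _pack(res.bse),
                              _pack(res.pvalues),
                              float(np.asarray(res.cov_re)[0, 0]),
                              float(res.scale), int(res.nobs),
                              True, method)
        # pooled OLS fallback (zero random-intercept variance limit)
        logger.warning("mixed model failed to converge; pooled OLS fallback")
        res = sm.OLS(y, X).fit()
        return LMEFit(_pack(res.params), _pack(res.bse), _pack(res.pvalues),
                      0.0, float(res.mse_resid), int(res.nobs),
                      False, "ols")


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        control: np.ndarray) -> tuple[float, int, float]:
    """Pearson partial correlation of x and y controlling one covariate.

    Residual-on-residual formulation; two-sided p from t with
    df = n − 3.
    """
    x, y, control = (np.asarray(a, dtype=float) for a in (x, y, control))
    n = len(x)
    if control.std() == 0 or x.std() == 0:
        raise ValueError("zero-variance covariate")
    Z = np.column_stack([np.ones(n), control])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx < 1e-12 * max(np.abs(x).max(), 1e-300) or \
            ny < 1e-12 * max(np.abs(y).max(), 1e-300):
        # a variable fully explained by the control has no residual
        # association left
        r = 0.0
    else:
        r = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, df, float(p)


@dataclass
class CorrelationCluster:
    """A surviving cluster of the voxel-wise correlation map."""

    voxels: np.ndarray               # member voxel indices
    peak_voxel: int                  # member with max |r|
    peak_r: float
    sign: int


@dataclass
class CorrelationMapResult:
    r: np.ndarray
    p: np.ndarray
    df: int
    clusters: list[CorrelationCluster]


def whole_brain_partial_correlation(images: np.ndarray, x: np.ndarray,
                                    control: np.ndarray, grid: SourceGrid,
                                    alpha_vox: float = 0.001,
                                    k: int = 5) -> CorrelationMapResult:
    """Voxel-wise partial correlation map with cluster-extent correction.

    ``images`` is (n_subjects, n_voxels) of pseudo-t values, ``x`` the
    covariate of interest (e.g. weekly hearing-aid use) and ``control``
    the conditioning covariate (e.g. BEPTA).  Voxels significant at
    ``alpha_vox`` (two-sided, df = n − 3) are grouped by 6-face lattice
    adjacency, separately by sign; clusters of at least ``k`` voxels
    are reported with their peak (max |r|) member.
    """
    images = np.asarray(images, dtype=float)
    n, nv = images.shape
    if n < 6:
        raise ValueError("need at least 6 subjects with complete covariates")
    x = np.asarray(x, dtype=float)
    control = np.asarray(control, dtype=float)
    if control.std() == 0 or x.std() == 0:
        raise ValueError("zero-variance covariate")

    Z = np.column_stack([np.ones(n), control])
    proj = Z @ np.linalg.pinv(Z)
    rx = x - proj @ x
    ry = images - proj @ images
    rx_n = rx / np.linalg.norm(rx)
    norms = np.linalg.norm(ry, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx_n @ ry) / norms
    r = np.clip(np.where(norms > 0, r, 0.0), -1.0, 1.0)
    df = n - 3
    t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    clusters: list[CorrelationCluster] = []
    vol = np.zeros(grid.shape, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-face
    for sign in (1, -1):
        sig = (p < alpha_vox) & (np.sign(r) == sign)
        vol[:] = False
        vol[tuple(grid.ijk.T)] = sig
        labels, n_lab = ndimage.label(vol, structure=structure)
        vox_labels = labels[tuple(grid.ijk.T)]
        for lab in range(1, n_lab + 1):
            members = np.flatnonzero(vox_labels == lab)
            if members.size < k:
                continue
            peak = members[np.argmax(np.abs(r[members]))]
            clusters.append(CorrelationCluster(
                members, int(peak), float(r[peak]), sign))
    clusters.sort(key=lambda c: abs(c.peak_r), reverse=True)
    return CorrelationMapResult(r, p, df, clusters)


def peak_behavior_correlation(peak_values, scores
                              ) -> tuple[float, int, float]:
    """Pearson correlation between peak activity and a behavioral score."""
    x = np.asarray(peak_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired observations required")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    res = stats.pearsonr(x, y)
    return float(res.statistic), len(x) - 2, float(res.pvalue)


def pooled_t_from_summary(m1: float, sd1: float, n1: int,
                          m2: float, sd2: float, n2: int
                          ) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from group summary statistics.

    Convention: positive t when group 2 exceeds group 1.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty row or column in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def demographic_comparison(records: pd.DataFrame,
                           continuous: list[str] | None = None
                           ) -> pd.DataFrame:
    """Group comparisons of demographic/behavioral variables.

    Continuous variables get a pooled-variance t-test (CNH vs. CHH);
    sex gets a Pearson chi-square; handedness is collapsed to right
    vs. non-right before the chi-square.  Returns one row per variable
    with the statistic and p-value.
    """
    if continuous is None:
        continuous = [c for c in ("age", "verbal_score")
                      if c in records.columns]
    g = records.groupby("group")
    if g.ngroups < 2 or g.size().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for var in continuous:
        s = g[var].agg(["mean", "std", "count"])
        t, df, p = pooled_t_from_summary(
            s.loc["CNH", "mean"], s.loc["CNH", "std"],
            int(s.loc["CNH", "count"]),
            s.loc["CHH", "mean"], s.loc["CHH", "std"],
            int(s.loc["CHH", "count"]))
        rows.append((var, "pooled t", t, df, p))
    if "sex" in records.columns:
        tab = pd.crosstab(records["group"], records["sex"])
        chi2, dof, p = chi_square_independence(tab.values)
        rows.append(("sex", "chi-square", chi2, dof, p))
    if "handedness" in records.columns:
        right = records["handedness"].eq("R").map({True: "R", False: "non-R"})
        tab = pd.crosstab(records["group"], right)
        chi2, dof, p = chi_square_independence(tab.values)
        rows.append(("handedness", "chi-square", chi2, dof, p))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                       "df", "p_value"])
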