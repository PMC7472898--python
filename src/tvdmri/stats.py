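"""ROI statistics for group and clinical analyses of scalar maps.

Implements the statistics stage of the analysis: mask hygiene
(morphological erosion), per-ROI means, group-averaged histograms, the
FA-threshold sensitivity analysis, a hemisphere-by-group repeated-
measures (split-plot) ANOVA with age and sex as covariates, Pearson /
Spearman / partial correlations, and Bonferroni correction.

The mixed ANOVA follows the classical split-plot decomposition:

* between-subject stratum — subject means across hemispheres regressed
  on group + covariates (Sum-coded, Type-III sums of squares), giving
  the group main effect and covariate-adjusted pairwise group t-tests;
* within-subject stratum — hemisphere differences regressed on the same
  design, giving the hemisphere main effect (adjusted mean difference)
  and the hemisphere-by-group interaction.

This matches SPSS's Type-III behaviour on balanced designs; on
unbalanced designs the Sum-coded Type-III decomposition is the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .dti import ScalarMap

__all__ = [
    "erode_mask",
    "roi_mean",
    "masked_histogram",
    "fa_threshold_analysis",
    "rm_anova",
    "correlate",
    "bonferroni",
    "RoiSummary",
    "AnovaResult",
    "CorrelationResult",
]


@dataclass
class RoiSummary:
    subject_id: str
    roi: str
    hemisphere: str
    metric: str
    mean: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise ValueError("a reported ROI mean needs at least one voxel")
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("FA/uFA ROI mean must lie in [0, 1]")


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[float, float]
    p: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if self.F < 0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid F or p")


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    controls: tuple = ()
    defined: bool = True


# 6-connected structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, n_voxels: int) -> np.ndarray:
    """n iterations of 6-connected morphological erosion (n=0: unchanged)."""
    if n_voxels < 0:
        raise ValueError("erosion count must be non-negative")
    m = mask.astype(bool)
    if n_voxels == 0:
        return m.copy()
    return ndimage.binary_erosion(m, structure=_STRUCT6, iterations=n_voxels)


def roi_mean(
    scalar_map: ScalarMap, mask: np.ndarray, roi: str = "ROI",
    subject_id: str = "", hemisphere: str = "",
) -> RoiSummary:
    """Arithmetic mean over masked, validly fitted voxels.

    Lesion voxels must already be excluded from the mask (NAWM
    convention).  Raises if the mask does not overlap the map's valid
    region.
    """
    sel = mask.astype(bool) & scalar_map.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi!r} has no overlap with valid map voxels")
    return RoiSummary(subject_id, roi, hemisphere, scalar_map.metric,
                      float(scalar_map.data[sel].mean()), n)


def masked_histogram(
    maps: list[ScalarMap], masks: list[np.ndarray], bin_edges: np.ndarray | None = None
) -> np.ndarray:
    """Group-mean of per-subject density-normalised histograms.

    Each subject's histogram is normalised to unit sum, then averaged
    without weighting across subjects, so the group histogram also sums
    to one.  Defaults to 64 uniform bins on [0, 1].
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 65)
    hists = []
    for m, msk in zip(maps, masks):
        sel = msk.astype(bool) & m.mask
        h, _ = np.histogram(m.data[sel], bins=bin_edges)
        total = h.sum()
        hists.append(h / total if total > 0 else h.astype(float))
    return np.mean(hists, axis=0)


def fa_threshold_analysis(
    fa_map: ScalarMap,
    ufa_map: ScalarMap,
    mask: np.ndarray,
    thresholds=(0.0, 0.2, 0.4, 0.6),
) -> pd.DataFrame:
    """Means of FA and uFA after discarding voxels with FA <= threshold.

    Emulates the common practice of restricting WM ROIs to high-FA
    voxels; mean FA is non-decreasing in the threshold by construction.
    A threshold that empties the mask yields a flagged row (NaN means).
    """
    if fa_map.data.shape != ufa_map.data.shape:
        raise ValueError("FA and uFA maps must be co-registered")
    base = mask.astype(bool) & fa_map.mask & ufa_map.mask
    rows = []
    for t in thresholds:
        sel = base & (fa_map.data > t)
        n = int(sel.sum())
        rows.append(
            {
                "threshold": t,
                "n_voxels": n,
                "mean_fa": float(fa_map.data[sel].mean()) if n else np.nan,
                "mean_ufa": float(ufa_map.data[sel].mean()) if n else np.nan,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment min(1, m*p); m defaults to len(p_values)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mm = len(p) if m is None else int(m)
    if mm < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, mm * p)
    return float(out[0]) if np.isscalar(p_values) else out


def _between_design(df: pd.DataFrame, value_col: str):
    """Sum-coded OLS of ``value_col`` on group + centred covariates."""
    work = df.copy()
    work["age_c"] = work["age"] - work["age"].mean()
    work["sex_c"] = (work["sex"] == "F").astype(float)
    work["sex_c"] -= work["sex_c"].mean()
    model = smf.ols(f"{value_col} ~ C(group, Sum) + age_c + sex_c", data=work).fit()
    return model, work


def rm_anova(table: pd.DataFrame, metric: str, roi: str | None = None) -> dict[str, AnovaResult]:
    """Hemisphere-by-group split-plot ANOVA with age and sex covariates.

    ``table`` is a long table with columns id, group, age, sex,
    hemisphere and the metric column; subjects missing a hemisphere are
    dropped.  Returns AnovaResults for the effects ``group`` (with
    Bonferroni-adjusted pairwise group comparisons), ``hemisphere`` and
    ``hemisphere:group``.
    """
    df = table
    if roi is not None and "roi" in df.columns:
        df = df[df["roi"] == roi]
    wide = df.pivot_table(index=["id", "group", "age", "sex"], columns="hemisphere",
                          values=metric, aggfunc="mean").reset_index()
    missing = wide[["left", "right"]].isna().any(axis=1)
    if missing.any():
        wide = wide[~missing]
    if wide["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    wide = wide.copy()
    wide["subj_mean"] = wide[["left", "right"]].mean(axis=1)
    wide["hemi_diff"] = wide["left"] - wide["right"]

    results: dict[str, AnovaResult] = {}

    # between-subject stratum: group effect on hemisphere means
    model_b, work_b = _between_design(wide, "subj_mean")
    aov_b = anova_lm(model_b, typ=3)
    f = float(aov_b.loc["C(group, Sum)", "F"])
    df1 = float(aov_b.loc["C(group, Sum)", "df"])
    df2 = float(aov_b.loc["Residual", "df"])
    p = float(aov_b.loc["C(group, Sum)", "PR(>F)"])
    results["group"] = AnovaResult("group", f, (df1, df2), p,
                                   pairwise=_pairwise_groups(work_b, "subj_mean"))

    # within-subject stratum: hemisphere main effect and interaction on
    # hemisphere differences
    model_w, work_w = _between_design(wide, "hemi_diff")
    aov_w = anova_lm(model_w, typ=3)
    f_int = float(aov_w.loc["C(group, Sum)", "F"])
    p_int = float(aov_w.loc["C(group, Sum)", "PR(>F)"])
    results["hemisphere:group"] = AnovaResult(
        "hemisphere:group", f_int,
        (float(aov_w.loc["C(group, Sum)", "df"]), float(aov_w.loc["Residual", "df"])),
        p_int,
    )
    # hemisphere main effect: adjusted mean difference = model intercept
    # (Sum coding + centred covariates)
    t_h = model_w.t_test("Intercept")
    f_h = float(np.asarray(t_h.tvalue).ravel()[0]) ** 2
    results["hemisphere"] = AnovaResult(
        "hemisphere", f_h, (1.0, float(model_w.df_resid)),
        float(np.asarray(t_h.pvalue).ravel()[0]),
    )
    return results


def _pairwise_groups(work: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Covariate-adjusted pairwise group contrasts, Bonferroni-corrected.

    Contrasts are tested in the same Sum-coded OLS via linear hypotheses
    on the group effects; m = number of pairwise contrasts.
    """
    groups = sorted(work["group"].unique())
    model = smf.ols(f"{value_col} ~ C(group, levels={groups!r}) + age_c + sex_c",
                    data=work).fit()
    names = model.params.index
    rows = []
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        vec = np.zeros(len(names))
        for g, sign in ((a, 1.0), (b, -1.0)):
            if g == groups[0]:
                continue  # reference level: coefficient 0
            col = f"C(group, levels={groups!r})[T.{g}]"
            vec[list(names).index(col)] = sign
        tt = model.t_test(vec)
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": float(np.asarray(tt.effect).ravel()[0]),
                "t": float(np.asarray(tt.tvalue).ravel()[0]),
                "p": float(np.asarray(tt.pvalue).ravel()[0]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonf"] = bonferroni(out["p"].to_numpy(), m=len(pairs))
    return out


def correlate(x, y, method: str = "pearson", control=None) -> CorrelationResult:
    """Pearson / Spearman / partial-Pearson correlation with two-sided p.

    Spearman uses average ranks for ties; the partial correlation
    residualises both variables on the control covariates and applies
    Pearson to the residuals, with the p-value from the t transform on
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    controls = []
    if control is not None:
        controls = [np.asarray(c, dtype=float) for c in np.atleast_2d(control)]
        for c in controls:
            keep &= np.isfinite(c)
    x, y = x[keep], y[keep]
    controls = [c[keep] for c in controls]
    n = len(x)
    k = len(controls)
    if n < 3 + k:
        raise ValueError(f"need at least {3 + k} complete observations, got {n}")

    def _undefined(m):
        return CorrelationResult(m, float("nan"), float("nan"), n,
                                 tuple(range(k)), defined=False)

    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        method_used = "spearman"
    elif method == "pearson" and k == 0:
        method_used = "pearson"
    elif method in ("pearson", "partial_pearson") and k > 0:
        Z = np.column_stack([np.ones(n)] + controls)
        for c in controls:
            if np.ptp(c) == 0:
                return _undefined("partial_pearson")
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        method_used = "partial_pearson"
    elif method == "partial_pearson":
        method_used = "pearson"  # no controls supplied
    else:
        raise ValueError(f"unknown method {method!r}")

    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return _undefined(method_used)
    r = float(np.corrcoef(x, y)[0, 1])
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return CorrelationResult(method_used, r, p, n, tuple(range(k)))
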