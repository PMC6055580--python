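"""Statistical comparison of depth distributions.

Each experiment (real or simulated) is summarized by its mean depth; groups
of experiments are compared by ANCOVA with overall population density as
the covariate: first a test of slope homogeneity (density-by-group
interaction), then — only when the slopes do not differ — a test of the
intercepts under the common-slope model.  Families of comparisons use a
Bonferroni-adjusted per-comparison level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .column import SectorColumn

__all__ = [
    "ComparisonResult",
    "mean_depth",
    "density_regression",
    "compare_groups",
    "bonferroni_alpha",
    "run_comparison_battery",
    "EXPERIMENT_COMPARISONS",
]


class AnalysisError(ValueError):
    """Raised for degenerate comparison inputs."""


def mean_depth(distribution, column: SectorColumn) -> float:
    """Depth of the center of mass: sum of fraction_i * midpoint_i (m)."""
    frac = np.asarray(distribution, dtype=float)
    if frac.shape != (column.n_sectors,):
        raise AnalysisError("distribution length must match the column")
    if not np.isclose(frac.sum(), 1.0, rtol=0, atol=1e-6):
        raise AnalysisError("distribution fractions must sum to 1")
    return float(frac @ column.midpoints)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    r_squared: float
    n: int


def density_regression(records: pd.DataFrame) -> RegressionResult:
    """OLS of mean depth on overall population density for one group."""
    if len(records) < 3 or records["density"].nunique() < 2:
        raise AnalysisError(
            "need >= 3 records with >= 2 distinct densities"
        )
    X = sm.add_constant(records["density"].to_numpy(dtype=float))
    fit = sm.OLS(records["mean_depth"].to_numpy(dtype=float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]), slope_p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared), n=len(records),
    )


@dataclass
class ComparisonResult:
    """ANCOVA comparison of two groups of experiments.

    The intercept test is computed under the pooled-slope model and is
    reported only when the slopes do not differ at ``alpha`` (the
    ``intercept_reported`` flag); its statistics are retained either way.
    """

    label: str
    slope_F: float
    slope_df: tuple
    slope_p: float
    intercept_F: float
    intercept_df: tuple
    intercept_p: float
    intercept_reported: bool
    group_fits: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def slope_significant(self) -> bool:
        return self.slope_p < self.alpha

    @property
    def intercept_significant(self) -> bool:
        return self.intercept_reported and self.intercept_p < self.alpha


def compare_groups(
    records: pd.DataFrame,
    grouping: str = "group",
    alpha: float = 0.05,
    label: str = "",
) -> ComparisonResult:
    """ANCOVA of mean depth on density between two groups.

    Step 1 tests slope homogeneity (the density x group interaction F).
    Step 2 tests the group intercepts under the common-slope model; its
    result is flagged as not-reported when the slopes differ.
    """
    df = records.rename(columns={grouping: "group"}).copy()
    levels = df["group"].unique()
    if len(levels) != 2:
        raise AnalysisError(f"grouping must have 2 levels, got {list(levels)}")
    fits = {}
    for lev in levels:
        fits[lev] = density_regression(df[df["group"] == lev])
    full = smf.ols("mean_depth ~ density * C(group)", data=df).fit()
    common = smf.ols("mean_depth ~ density + C(group)", data=df).fit()
    covar_only = smf.ols("mean_depth ~ density", data=df).fit()
    slope_tab = sm.stats.anova_lm(common, full)
    inter_tab = sm.stats.anova_lm(covar_only, common)
    slope_F = float(slope_tab["F"].iloc[1])
    slope_p = float(slope_tab["Pr(>F)"].iloc[1])
    inter_F = float(inter_tab["F"].iloc[1])
    inter_p = float(inter_tab["Pr(>F)"].iloc[1])
    # identical groups give SSE differences of exactly 0 -> F = 0, p = 1
    if not np.isfinite(slope_F):
        slope_F, slope_p = 0.0, 1.0
    if not np.isfinite(inter_F):
        inter_F, inter_p = 0.0, 1.0
    slope_sig = slope_p < alpha
    return ComparisonResult(
        label=label,
        slope_F=max(slope_F, 0.0),
        slope_df=(int(slope_tab["df_diff"].iloc[1]), int(full.df_resid)),
        slope_p=slope_p,
        intercept_F=max(inter_F, 0.0),
        intercept_df=(int(inter_tab["df_diff"].iloc[1]), int(common.df_resid)),
        intercept_p=inter_p,
        intercept_reported=not slope_sig,
        group_fits={str(k): v for k, v in fits.items()},
        alpha=alpha,
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison level family_alpha/m at 3 significant figures."""
    if not (0 < family_alpha < 1):
        raise AnalysisError("family_alpha must be in (0, 1)")
    if m < 1:
        raise AnalysisError("m must be >= 1")
    return float(np.format_float_positional(
        family_alpha / m, precision=3, unique=False, fractional=False
    ))


#: The 12 within-experiment comparisons: age contrasts within each
#: treatment, then treatment contrasts within each age class.
EXPERIMENT_COMPARISONS = (
    [("age", tr, None) for tr in ("none", "food", "risk", "both")]
    + [
        ("treatment", (a, t1, t2), None)
        for t1, t2 in (("none", "food"), ("none", "risk"),
                       ("food", "both"), ("risk", "both"))
        for a in ("juvenile", "adult")
    ]
)


def _safe_compare(records, grouping, alpha, label):
    try:
        return compare_groups(records, grouping, alpha, label)
    except AnalysisError as exc:
        return ComparisonResult(
            label=f"{label} [missing: {exc}]", slope_F=np.nan,
            slope_df=(0, 0), slope_p=np.nan, intercept_F=np.nan,
            intercept_df=(0, 0), intercept_p=np.nan,
            intercept_reported=False, group_fits={}, alpha=alpha,
        )


def _result_row(res: ComparisonResult, family: str, adj_alpha: float) -> dict:
    return {
        "family": family,
        "comparison": res.label,
        "slope_F": res.slope_F,
        "slope_df": f"{res.slope_df[0]};{res.slope_df[1]}",
        "slope_p": res.slope_p,
        "slope_significant": bool(np.isfinite(res.slope_p) and res.slope_p < adj_alpha),
        "intercept_F": res.intercept_F if res.intercept_reported else np.nan,
        "intercept_df": (
            f"{res.intercept_df[0]};{res.intercept_df[1]}"
            if res.intercept_reported else ""
        ),
        "intercept_p": res.intercept_p if res.intercept_reported else np.nan,
        "intercept_significant": bool(
            res.intercept_reported
            and np.isfinite(res.intercept_p)
            and res.intercept_p < adj_alpha
        ),
        "missing": res.group_fits == {},
    }


def run_comparison_battery(
    records: pd.DataFrame, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Run the full comparison battery over experiment/simulation records.

    Records need columns source ('experiment', 'simulation-II',
    'simulation-III'), treatment, age, density, mean_depth.  The
    experiment-side family holds the 12 age/treatment contrasts (adjusted
    level family_alpha/12); the model-verification family compares
    experiments against each simulation variant within every treatment x
    age cell, adjusted for the 4 within-age treatment comparisons.
    Empty cells yield explicit missing rows rather than errors.
    """
    rows = []
    exp = records[records["source"] == "experiment"]
    a12 = bonferroni_alpha(family_alpha, 12)
    for kind, spec_, _ in EXPERIMENT_COMPARISONS:
        if kind == "age":
            tr = spec_
            sub = exp[exp["treatment"] == tr].copy()
            sub["group"] = sub["age"]
            label = f"juvenile vs adult, treatment={tr}"
        else:
            age, t1, t2 = spec_
            sub = exp[(exp["age"] == age) & (exp["treatment"].isin([t1, t2]))].copy()
            sub["group"] = sub["treatment"]
            label = f"{age}: {t1} vs {t2}"
        res = _safe_compare(sub, "group", a12, label)
        rows.append(_result_row(res, "experiment", a12))

    a4 = bonferroni_alpha(family_alpha, 4)
    for age in ("juvenile", "adult"):
        for rtype in ("II", "III"):
            sim_source = f"simulation-{rtype}"
            for tr in ("none", "food", "risk", "both"):
                sub = records[
                    (records["age"] == age)
                    & (records["treatment"] == tr)
                    & (records["source"].isin(["experiment", sim_source]))
                ].copy()
                sub["group"] = sub["source"]
                label = f"{age}, {tr}: experiment vs {sim_source}"
                if sub["group"].nunique() == 2:
                    res = _safe_compare(sub, "group", a4, label)
                else:
                    res = _safe_compare(sub.iloc[0:0], "group", a4, label)
                rows.append(_result_row(res, f"verification-{rtype}", a4))
    return pd.DataFrame(rows)


def battery_text_report(battery: pd.DataFrame) -> str:
    """Human-readable rendering of the battery table."""
    lines = []
    for fam, part in battery.groupby("family", sort=False):
        lines.append(f"== {fam} ==")
        for _, r in part.iterrows():
            star = "*" if (r["slope_significant"] or r["intercept_significant"]) else " "
            if r["missing"]:
                lines.append(f" {star} {r['comparison']}: MISSING DATA")
                continue
            s = (f" {star} {r['comparison']}: slopes F={r['slope_F']:.2f} "
                 f"({r['slope_df']}) p={r['slope_p']:.4f}")
            if r["intercept_df"]:
                s += (f"; intercepts F={r['intercept_F']:.2f} "
                      f"({r['intercept_df']}) p={r['intercept_p']:.4f}")
            else:
                s += "; intercepts not shown (slopes differ)"
            lines.append(s)
    return "\n".join(lines)
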