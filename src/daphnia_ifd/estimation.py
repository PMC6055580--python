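"""Least-squares fits of the model's parameter relationships to trial data.

Covers the four parameterization experiments: the predator's functional
response (type II vs. III, with an extra-sum-of-squares model comparison),
the growth-rate surface over food/density/light/age/kairomone, the
reaction-distance model over light/spectral band/age, and the perception
cost (growth slowdown in a food gradient relative to a homogeneous column).

All fits are ordinary least squares.  The threshold parameters of the
type III response create flat, multimodal error surfaces, so the
functional-response fit is multi-started from a coarse data-driven grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rates import ADULT, FunctionalResponseParams, GrowthParams, RDParams

__all__ = [
    "FitResult",
    "ResponseSelection",
    "PerceptionCostResult",
    "fit_functional_response",
    "compare_response_types",
    "to_per_capita_risk",
    "scale_gamma_for_age",
    "fit_growth_model",
    "fit_reaction_distance_model",
    "estimate_perception_cost",
]


class FitFailureError(RuntimeError):
    """Raised when no optimizer start converges."""


class DataError(ValueError):
    """Raised for datasets that cannot identify the requested model."""


@dataclass
class FitResult:
    """Outcome of one least-squares fit."""

    params: object
    param_names: list
    estimates: np.ndarray
    se: np.ndarray
    sse: float
    dof: int
    selected_type: str | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.estimates / self.se
        p = 2 * stats.t.sf(np.abs(t), self.dof)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.estimates,
                "se": self.se,
                "t": t,
                "p": p,
            }
        )

    def wald_p(self, name: str, null: float = 0.0) -> float:
        i = self.param_names.index(name)
        if self.se[i] == 0:
            return 0.0 if self.estimates[i] != null else 1.0
        t = (self.estimates[i] - null) / self.se[i]
        return float(2 * stats.t.sf(abs(t), self.dof))


def _ls_se(result, n_obs: int) -> tuple[np.ndarray, float, int]:
    """Standard errors from the least-squares Jacobian at the solution."""
    sse = float(2 * result.cost)
    n_par = len(result.x)
    dof = max(n_obs - n_par, 1)
    s2 = sse / dof
    J = result.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    return se, sse, dof


# ---------------------------------------------------------------------------
# Functional response
# ---------------------------------------------------------------------------


def _fr_model(N, a, h, gamma, n):
    M = np.maximum(N - gamma, 0.0)
    Mn = M**n
    return a * Mn / (1.0 + a * h * Mn)


def _fr_starts(N, C, response_type):
    """Coarse multi-start grid: slope through low-density points for the
    attack rate, 1/max(C) for handling, the largest density with ~zero
    consumption for gamma, n in {1, 2, 3}."""
    order = np.argsort(N)
    N_s, C_s = N[order], C[order]
    low = N_s > 0
    a0 = float(np.median(C_s[low][:4] / N_s[low][:4])) if low.sum() >= 2 else 1.0
    a0 = max(a0, 1e-6)
    cmax = float(C.max())
    h0 = 1.0 / cmax if cmax > 0 else 1e-3
    zeros = N_s[C_s <= 0.02 * max(cmax, 1e-12)]
    g_data = float(zeros.max()) if len(zeros) else 0.0
    if response_type == "II":
        return [(a0, h0), (a0, h0 / 10), (10 * a0, h0), (a0 / 10, h0)]
    starts = []
    for g0 in {0.0, g_data}:
        for n0 in (1.0, 2.0, 3.0):
            starts.append((a0, h0, g0, n0))
            starts.append((10 * a0, h0, g0, n0))
    return starts


def fit_functional_response(
    data: pd.DataFrame, response_type: str = "II"
) -> FitResult:
    """Fit the threshold disc equation to (prey_density, consumption) rows.

    Type II fixes gamma = 0 and n = 1 (Holling's disc equation); type III
    frees the foraging-initiation threshold gamma >= 0 and the shape
    exponent n >= 1.
    """
    if response_type not in ("II", "III"):
        raise DataError("response_type must be 'II' or 'III'")
    N = np.asarray(data["prey_density"], dtype=float)
    C = np.asarray(data["consumption"], dtype=float)
    min_rows = 4 if response_type == "II" else 6
    if len(N) < min_rows or len(np.unique(N)) < 3:
        raise DataError(
            f"need >= {min_rows} rows spanning >= 3 distinct densities"
        )
    if (N < 0).any() or (C < 0).any():
        raise DataError("densities and consumption must be non-negative")

    if response_type == "II":
        def resid(theta):
            return _fr_model(N, theta[0], theta[1], 0.0, 1.0) - C
        bounds = ([1e-12, 0.0], [np.inf, np.inf])
        names = ["attack", "handling"]
    else:
        def resid(theta):
            return _fr_model(N, *theta) - C
        bounds = ([1e-12, 0.0, 0.0, 1.0], [np.inf, np.inf, np.inf, np.inf])
        names = ["attack", "handling", "gamma", "n"]

    best = None
    diagnostics = []
    for start in _fr_starts(N, C, response_type):
        try:
            res = optimize.least_squares(
                resid, np.asarray(start, dtype=float), bounds=bounds,
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {start}: {exc}")
            continue
        if not res.success:
            diagnostics.append(f"start {start}: {res.message}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError(
            "no start converged: " + "; ".join(diagnostics)
        )
    se, sse, dof = _ls_se(best, len(N))
    if response_type == "II":
        params = FunctionalResponseParams(
            attack=best.x[0], handling=best.x[1], type="II"
        )
    else:
        params = FunctionalResponseParams(
            attack=best.x[0], handling=best.x[1], gamma=best.x[2],
            n=best.x[3], type="III",
        )
    return FitResult(
        params=params, param_names=names, estimates=best.x.copy(),
        se=se, sse=sse, dof=dof, selected_type=response_type,
    )


@dataclass(frozen=True)
class ResponseSelection:
    """Extra-sum-of-squares comparison of nested response types."""

    selected: str
    F: float
    df_num: int
    df_den: int
    p: float
    aic_II: float
    aic_III: float
    alpha: float


def compare_response_types(
    fit_II: FitResult, fit_III: FitResult, n_obs: int, alpha: float = 0.05
) -> ResponseSelection:
    """Select between the nested type II and type III fits on one dataset.

    Primary criterion: the extra-sum-of-squares F-test on the two extra
    parameters (gamma, n); AIC is reported alongside.  With equal error the
    simpler type II is retained (parsimony).
    """
    if fit_II.selected_type != "II" or fit_III.selected_type != "III":
        raise DataError("pass a type II and a type III fit, in that order")
    if fit_II.dof - fit_III.dof != 2:
        raise DataError("fits do not look like they used the same data")
    df_num, df_den = 2, n_obs - 4
    sse2, sse3 = fit_II.sse, fit_III.sse
    # a numerically negligible improvement is no improvement (both fits at
    # machine-level error on noiseless data)
    if sse2 - sse3 <= 1e-10 * max(1.0, sse2):
        F = 0.0
    elif sse3 <= 0:
        F = np.inf
    else:
        F = max(sse2 - sse3, 0.0) / df_num / (sse3 / df_den)
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    def aic(sse, k):
        return n_obs * np.log(max(sse, 1e-300) / n_obs) + 2 * k

    selected = "III" if (p < alpha and sse3 < sse2) else "II"
    return ResponseSelection(
        selected=selected, F=float(F), df_num=df_num, df_den=df_den, p=p,
        aic_II=aic(sse2, 2), aic_III=aic(sse3, 4), alpha=alpha,
    )


def to_per_capita_risk(data: pd.DataFrame) -> pd.DataFrame:
    """Transform consumption rows to per-capita risk = consumption/density.

    Zero-density rows are dropped with a warning (risk undefined there).
    """
    N = np.asarray(data["prey_density"], dtype=float)
    keep = N > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-density rows", stacklevel=2
        )
    out = data.loc[keep].copy()
    out["per_capita_risk"] = out["consumption"] / out["prey_density"]
    return out


def scale_gamma_for_age(gamma_fit: float, orders: int) -> float:
    """Reduce a fitted foraging-initiation threshold by whole orders of
    magnitude (the adult threshold is the juvenile best fit reduced by two
    orders), reported at 3 significant figures."""
    if gamma_fit < 0:
        raise DataError("gamma must be >= 0")
    scaled = gamma_fit * 10.0 ** (-orders)
    if scaled == 0:
        return 0.0
    return float(np.format_float_positional(
        scaled, precision=3, unique=False, fractional=False
    ))


# ---------------------------------------------------------------------------
# Growth model
# ---------------------------------------------------------------------------

_GROWTH_FACTORS = {
    "b": "density",
    "c": "light",
    "u": "light x age interaction",
    "kappa": "kairomone",
}


def _growth_design(data: pd.DataFrame):
    food = np.asarray(data["food"], dtype=float)
    density = np.asarray(data["density"], dtype=float)
    light = np.asarray(data["light"], dtype=float)
    adult = (data["age"] == ADULT).to_numpy().astype(float)
    kairo = np.asarray(data["kairomone"], dtype=bool).astype(float)
    gr = np.asarray(data["growth_rate"], dtype=float)
    return food, density, light, adult, kairo, gr


def fit_growth_model(data: pd.DataFrame, require_full: bool = False) -> FitResult:
    """Fit the growth surface g0 + a1*F/(a2+F) - b*D - (c + u*[adult]) *
    log10(1+light) - kappa*[kairomone] by nonlinear least squares.

    Factors without variation in the data are dropped (their coefficients
    fixed at 0) and named in the result; with ``require_full`` their absence
    raises an identifiability error instead.  Wald tests per coefficient
    allow the "coefficient differs from zero" conclusions to be replicated
    on synthetic data.
    """
    food, density, light, adult, kairo, gr = _growth_design(data)
    if len(np.unique(food)) < 2:
        raise DataError("need >= 2 food levels to identify a1/a2")
    loglight = np.log10(1.0 + light)
    active = {
        "b": len(np.unique(density)) >= 2,
        "c": len(np.unique(loglight)) >= 2,
        "u": len(np.unique(loglight)) >= 2 and len(np.unique(adult)) >= 2,
        "kappa": len(np.unique(kairo)) >= 2,
    }
    dropped = [k for k, v in active.items() if not v]
    if dropped and require_full:
        raise DataError(
            "unidentifiable terms (no variation): "
            + ", ".join(_GROWTH_FACTORS[k] for k in dropped)
        )

    names = ["g0", "a1", "a2"] + [k for k in ("b", "c", "u", "kappa") if active[k]]

    def unpack(theta):
        full = dict(zip(names, theta))
        return {k: full.get(k, 0.0) for k in ("g0", "a1", "a2", "b", "c", "u", "kappa")}

    def resid(theta):
        p = unpack(theta)
        mu = (
            p["g0"]
            + p["a1"] * food / (p["a2"] + food)
            - p["b"] * density
            - (p["c"] + p["u"] * adult) * loglight
            - p["kappa"] * kairo
        )
        return mu - gr

    gmax, gmin = float(gr.max()), float(gr.min())
    theta0 = {"g0": gmin, "a1": max(gmax - gmin, 0.1),
              "a2": float(np.median(food[food > 0])) if (food > 0).any() else 0.1,
              "b": 0.0, "c": 0.0, "u": 0.0, "kappa": 0.0}
    lb = {"g0": -np.inf, "a1": 0.0, "a2": 1e-8, "b": -np.inf, "c": -np.inf,
          "u": -np.inf, "kappa": -np.inf}
    x0 = np.array([theta0[k] for k in names])
    bounds = (np.array([lb[k] for k in names]), np.full(len(names), np.inf))
    res = optimize.least_squares(
        resid, x0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitFailureError(f"growth fit failed: {res.message}")
    J = res.jac
    if np.linalg.matrix_rank(J) < len(names):
        sv = np.linalg.svd(J, compute_uv=False)
        bad = [names[i] for i in range(len(names)) if i >= np.sum(sv > 1e-10 * sv[0])]
        raise DataError(f"rank-deficient design; confounded terms near: {bad}")
    se, sse, dof = _ls_se(res, len(gr))
    p = unpack(res.x)
    # raw estimates keep their sign; the params object clips to the
    # physical domain so it can drive the simulator directly
    params = GrowthParams(**{
        **p, "a1": max(p["a1"], 0.0), "b": max(p["b"], 0.0),
    })
    return FitResult(
        params=params, param_names=names, estimates=res.x.copy(), se=se,
        sse=sse, dof=dof, extras={"dropped_terms": dropped},
    )


# ---------------------------------------------------------------------------
# Reaction distance
# ---------------------------------------------------------------------------

_BAND_COLS = {"red": 0, "green": 1, "blue": 2}


def fit_reaction_distance_model(data: pd.DataFrame) -> FitResult:
    """Fit RD = (r0 + k*log10(1+light) + l*[adult]) * band factor.

    The band factor is w_red*alpha + w_green + w_blue*phi with the green
    multiplier fixed at 1 (the identification gauge).  Rows carry either a
    categorical ``band`` column (pure red/green/blue) or explicit
    w_red/w_green/w_blue weights.  The result's Wald contrasts against 1
    are the red-vs-green (alpha) and blue-vs-green (phi) band tests.
    """
    light = np.asarray(data["light"], dtype=float)
    adult = (data["age"] == ADULT).to_numpy().astype(float)
    rd = np.asarray(data["rd"], dtype=float)
    if "band" in data.columns:
        W = np.zeros((len(data), 3))
        for name, j in _BAND_COLS.items():
            W[(data["band"] == name).to_numpy(), j] = 1.0
        if not np.allclose(W.sum(axis=1), 1.0):
            raise DataError("band column must be red/green/blue")
    else:
        W = data[["w_red", "w_green", "w_blue"]].to_numpy(dtype=float)
    if len(np.unique(light)) < 2 or len(np.unique(W, axis=0)) < 2:
        raise DataError("need >= 2 light levels and >= 2 spectral bands")
    loglight = np.log10(1.0 + light)

    def resid(theta):
        r0, k, l, alpha, phi = theta
        base = r0 + k * loglight + l * adult
        bf = W[:, 0] * alpha + W[:, 1] + W[:, 2] * phi
        return base * bf - rd

    x0 = np.array([max(rd.min(), 0.1), 1.0, 0.0, 0.8, 1.0])
    bounds = ([0.0, -np.inf, -np.inf, 1e-6, 1e-6],
              [np.inf, np.inf, np.inf, np.inf, np.inf])
    res = optimize.least_squares(
        resid, x0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitFailureError(f"reaction-distance fit failed: {res.message}")
    se, sse, dof = _ls_se(res, len(rd))
    names = ["r0", "k", "l", "alpha", "phi"]
    params = RDParams(
        r0=res.x[0], k=res.x[1], l=res.x[2],
        alpha=min(res.x[3], 1.0), phi=res.x[4],
    )
    fit = FitResult(
        params=params, param_names=names, estimates=res.x.copy(), se=se,
        sse=sse, dof=dof,
    )
    fit.extras["p_red_vs_green"] = fit.wald_p("alpha", null=1.0)
    fit.extras["p_blue_vs_green"] = fit.wald_p("phi", null=1.0)
    return fit


# ---------------------------------------------------------------------------
# Perception cost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerceptionCostResult:
    """Percent growth slowdown in the gradient arm vs. the homogeneous arm."""

    percent_slowdown: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    mean_homogeneous: float
    mean_gradient: float
    sd_homogeneous: float
    sd_gradient: float
    n_homogeneous: int
    n_gradient: int


def estimate_perception_cost(
    data: pd.DataFrame, age: str | None = None, ci_level: float = 0.95
) -> PerceptionCostResult:
    """Growth slowdown caused by imperfect food assessment.

    ``data`` holds columns ``arrangement`` ('homogeneous' or 'gradient'),
    ``growth_rate`` and optionally ``age``.  Returns
    100*(mean_hom - mean_grad)/mean_hom with a Welch two-sample test and
    the per-arrangement standard deviations.
    """
    if age is not None:
        data = data[data["age"] == age]
    hom = np.asarray(
        data.loc[data["arrangement"] == "homogeneous", "growth_rate"], dtype=float
    )
    grad = np.asarray(
        data.loc[data["arrangement"] == "gradient", "growth_rate"], dtype=float
    )
    if len(hom) < 2 or len(grad) < 2:
        raise DataError("need >= 2 observations per arrangement")
    mh, mg = hom.mean(), grad.mean()
    if mh == 0:
        raise DataError("homogeneous-arm mean growth is zero")
    pct = 100.0 * (mh - mg) / mh
    welch = stats.ttest_ind(hom, grad, equal_var=False)
    # CI for the difference, scaled to percent of the homogeneous mean
    se_diff = np.sqrt(hom.var(ddof=1) / len(hom) + grad.var(ddof=1) / len(grad))
    df = welch.df
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
    lo = 100.0 * ((mh - mg) - tcrit * se_diff) / mh
    hi = 100.0 * ((mh - mg) + tcrit * se_diff) / mh
    return PerceptionCostResult(
        percent_slowdown=float(pct), ci_low=float(lo), ci_high=float(hi),
        t=float(welch.statistic), p=float(welch.pvalue),
        mean_homogeneous=float(mh), mean_gradient=float(mg),
        sd_homogeneous=float(hom.std(ddof=1)), sd_gradient=float(grad.std(ddof=1)),
        n_homogeneous=len(hom), n_gradient=len(grad),
    )
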