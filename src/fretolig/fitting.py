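"""Oligomer-order selection and dissociation-constant fitting.

The measured triplets (donor density, acceptor density, apparent FRET
efficiency) are confronted with the monomer/n-mer forward model for each
oligomer order n = 2..6.  For each n a grid search over the intrinsic FRET
E~ and the association constant K yields the minimum mean squared error
(MSE) of the predicted vs measured efficiencies; the n with the lowest MSE
selects the model.  A strict MSE minimum at n = 2 identifies a dimer
population, while a minimum at n > 2, or an essentially flat MSE profile
across orders, indicates clusters.  The grid-best parameters for the
selected order seed a nonlinear least-squares refinement that delivers
point estimates and 95% confidence intervals for E~ and K, the
dissociation constant Kdiss = 1/K, and the standard-state dissociation
free energy.

To keep the K grid commensurable across orders (K carries units that
depend on n), the grid is parametrised by the *half-saturation density*:
the total receptor density at which half the protomers are oligomeric.
For a dimer this density equals Kdiss exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .equilibrium import (
    OligomerModel,
    ThermoContext,
    _binomial_basis,
    _pair_weights,
    assoc_const_for_fraction,
    delta_g,
    monomer_concentration,
)
from .errors import InsufficientDesignError, NonConvergenceError
from .proximity import ProximityTable, proximity_at

__all__ = [
    "MeasurementSet",
    "ParameterGrid",
    "GridBest",
    "FitResult",
    "LinearityResult",
    "WelchComparison",
    "half_saturation_to_assoc_const",
    "mse_profile",
    "select_order",
    "refine_fit",
    "fit_oligomer_model",
    "oligo_fraction_curve",
    "compare_kdiss",
    "fret_vs_acceptor_fraction",
]

_REQUIRED = ("donor_conc", "acceptor_conc", "fret_efficiency")


@dataclass
class MeasurementSet:
    """Per-membrane-region measurements for one experimental condition.

    Wraps a DataFrame with columns ``cell_id``, ``region_id``,
    ``donor_conc``, ``acceptor_conc``, ``fret_efficiency`` (densities in
    receptors/um^2) and optionally ``ratio`` (donor:acceptor transfection
    ratio label).  ``n_experiments`` is the number of independent
    experiments pooled into the set; it supplies the degrees of freedom of
    between-condition Welch tests.
    """

    data: pd.DataFrame
    condition: str = ""
    n_experiments: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("measurement set is empty")
        df = self.data
        if (df["donor_conc"] < 0).any() or (df["acceptor_conc"] < 0).any():
            raise ValueError("concentrations must be nonnegative")
        if ((df["fret_efficiency"] < 0) | (df["fret_efficiency"] > 1)).any():
            raise ValueError("efficiencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def donor(self) -> np.ndarray:
        return self.data["donor_conc"].to_numpy(dtype=float)

    @property
    def acceptor(self) -> np.ndarray:
        return self.data["acceptor_conc"].to_numpy(dtype=float)

    @property
    def efficiency(self) -> np.ndarray:
        return self.data["fret_efficiency"].to_numpy(dtype=float)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def acceptor_fraction(self) -> np.ndarray:
        return self.acceptor / self.total

    @property
    def donor_fraction(self) -> np.ndarray:
        return self.donor / self.total

    @property
    def n_cells(self) -> int:
        if "cell_id" in self.data.columns:
            return int(self.data["cell_id"].nunique())
        return 0


def half_saturation_to_assoc_const(n: int, half_sat: float) -> float:
    """Association constant whose n-mer curve is half-saturated at ``half_sat``.

    For n = 2 this returns ``1/half_sat``, i.e. the half-saturation density
    is the dimer dissociation constant.
    """
    return assoc_const_for_fraction(n, half_sat, 0.5)


def _default_half_sat_grid() -> np.ndarray:
    return np.logspace(-1, 5, 61)


def _default_e_tilde_grid() -> np.ndarray:
    return np.arange(0.01, 1.00, 0.01)


@dataclass(frozen=True)
class ParameterGrid:
    """Search grids for the (E~, K) plane, shared across oligomer orders.

    ``e_tilde`` covers (0, 1) at 0.01 resolution; ``half_saturation`` is
    log-spaced over six decades of total receptor density (receptors/um^2)
    and maps to an order-specific K.
    """

    e_tilde: np.ndarray = field(default_factory=_default_e_tilde_grid)
    half_saturation: np.ndarray = field(default_factory=_default_half_sat_grid)

    def __post_init__(self) -> None:
        e = np.asarray(self.e_tilde, dtype=float)
        h = np.asarray(self.half_saturation, dtype=float)
        if e.size == 0 or h.size == 0:
            raise ValueError("parameter grids must be nonempty")
        if np.any((e <= 0) | (e >= 1)):
            raise ValueError("E~ grid must lie in (0, 1)")
        if np.any(h <= 0):
            raise ValueError("half-saturation grid must be positive")
        object.__setattr__(self, "e_tilde", e)
        object.__setattr__(self, "half_saturation", h)


@dataclass(frozen=True)
class GridBest:
    """Grid-search optimum for one oligomer order."""

    n: int
    mse: float
    e_tilde: float
    assoc_const: float
    half_saturation: float


def _prox_per_point(data: MeasurementSet, proximity: Optional[ProximityTable]) -> np.ndarray:
    if proximity is None:
        return np.zeros(len(data))
    return np.asarray(proximity_at(proximity, data.acceptor), dtype=float)


def _apparent_matrix(
    n: int,
    assoc_const: float,
    w_matrix: np.ndarray,
    basis: np.ndarray,
    total: np.ndarray,
    x_d: np.ndarray,
    prox: np.ndarray,
) -> np.ndarray:
    """Model apparent efficiencies, shape (n_points, n_e_tilde)."""
    m = monomer_concentration(total, n, assoc_const)
    f = np.where(total > 0, n * assoc_const * m**n / np.maximum(total, 1e-300), 0.0)
    coef = f / (n * x_d)
    e_oligo = coef[:, None] * (basis @ w_matrix.T)
    return e_oligo + ((1.0 - f) * prox)[:, None]


def mse_profile(
    data: MeasurementSet,
    proximity: Optional[ProximityTable] = None,
    grid: ParameterGrid = ParameterGrid(),
    n_values: Iterable[int] = range(2, 7),
) -> Dict[int, GridBest]:
    """Minimum-MSE grid search over (E~, K) for each oligomer order.

    For every order n the model apparent efficiency is evaluated at each
    grid node for every measured region and compared with the measured
    efficiency; the per-order minimum of the mean squared residual and its
    arg-min parameters are returned.
    """
    if np.any(data.donor <= 0):
        raise ValueError("fitting requires donor-positive regions (donor-measured FRET)")
    total = data.total
    x_d = data.donor_fraction
    x_a = data.acceptor_fraction
    e_meas = data.efficiency
    prox = _prox_per_point(data, proximity)

    out: Dict[int, GridBest] = {}
    for n in n_values:
        basis = _binomial_basis(n, x_d, x_a)
        w = _pair_weights(n, grid.e_tilde)  # (n_e, n-1)
        best = (np.inf, None, None)
        for h in grid.half_saturation:
            k_assoc = half_saturation_to_assoc_const(n, h)
            e_model = _apparent_matrix(n, k_assoc, w, basis, total, x_d, prox)
            mse = np.mean((e_model - e_meas[:, None]) ** 2, axis=0)
            j = int(np.argmin(mse))
            if mse[j] < best[0]:
                best = (float(mse[j]), float(grid.e_tilde[j]), float(h))
        out[n] = GridBest(
            n=n,
            mse=best[0],
            e_tilde=best[1],
            assoc_const=half_saturation_to_assoc_const(n, best[2]),
            half_saturation=best[2],
        )
    return out


def select_order(
    mse_by_n: Mapping[int, float], rel_tol: float = 0.02
) -> Tuple[int, str]:
    """Classify the MSE-vs-order profile as dimer, cluster or ambiguous.

    A strict minimum at n = 2 (all higher orders worse by more than
    ``rel_tol`` relative to the minimum) indicates a dimer population; a
    minimum at n > 2 indicates clusters.  A profile that is flat across
    all orders also indicates clusters (large oligomers fit as well as any
    order), while a minimum at n = 2 with only some higher orders tied is
    reported as ambiguous.  Exact ties on the minimum resolve to the
    larger order (the cluster side).
    """
    orders = sorted(mse_by_n)
    values = np.array([mse_by_n[n] for n in orders], dtype=float)
    min_mse = float(values.min())
    # tie -> larger n
    best_n = int(max(o for o, v in zip(orders, values) if v == min_mse))
    tol = rel_tol * min_mse
    near = {o for o, v in zip(orders, values) if v - min_mse <= tol}
    if near == set(orders) and len(orders) > 1:
        return best_n, "cluster"
    if best_n > 2:
        return best_n, "cluster"
    if near == {2}:
        return 2, "dimer"
    return 2, "ambiguous"


@dataclass(frozen=True)
class FitResult:
    """Full outcome of the order-selection + refinement pipeline.

    Confidence intervals are 95%, from the linearised (Wald) covariance of
    the least-squares fit; the Kdiss interval is the reciprocal image of
    the K interval.  ``kdiss`` has units ``(receptors/um^2)^(n-1)``
    (receptors/um^2 for a dimer).
    """

    mse_by_n: Dict[int, float]
    best_n: int
    classification: str
    e_tilde: float
    e_tilde_ci: Tuple[float, float]
    assoc_const: float
    kdiss: float
    kdiss_ci: Tuple[float, float]
    delta_g: float
    delta_g_ci: Tuple[float, float]
    refined_mse: float
    n_points: int
    n_experiments: Optional[int] = None
    condition: str = ""
    temperature: float = 298.15
    wide_kdiss_ci: bool = False

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "mse_by_n": {str(k): v for k, v in self.mse_by_n.items()},
            "best_n": self.best_n,
            "classification": self.classification,
            "e_tilde": self.e_tilde,
            "e_tilde_ci95": list(self.e_tilde_ci),
            "assoc_const": self.assoc_const,
            "kdiss": self.kdiss,
            "kdiss_ci95": list(self.kdiss_ci),
            "delta_g_kcal_mol": self.delta_g,
            "delta_g_ci95": list(self.delta_g_ci),
            "refined_mse": self.refined_mse,
            "n_points": self.n_points,
            "n_experiments": self.n_experiments,
            "temperature_K": self.temperature,
            "wide_kdiss_ci": self.wide_kdiss_ci,
        }


def refine_fit(
    data: MeasurementSet,
    proximity: Optional[ProximityTable],
    n_fixed: int,
    start: GridBest,
    mse_by_n: Optional[Mapping[int, float]] = None,
    classification: str = "",
    temperature: float = 298.15,
) -> FitResult:
    """Nonlinear least-squares refinement of (E~, K) at fixed oligomer order.

    Starts from the grid optimum, optimises in (E~, ln K) for conditioning,
    and reports Wald 95% confidence intervals obtained from the Jacobian
    mapped back to the (E~, K) scale (t-quantile times standard error).
    The Kdiss interval is the reciprocal of the K interval; if the K
    interval reaches zero the upper Kdiss bound is unbounded and the result
    is flagged (``wide_kdiss_ci``), which occurs for saturated data that do
    not constrain the association strength.
    """
    total = data.total
    x_d = data.donor_fraction
    x_a = data.acceptor_fraction
    e_meas = data.efficiency
    prox = _prox_per_point(data, proximity)
    basis = _binomial_basis(n_fixed, x_d, x_a)
    n_pts = len(data)

    def residuals(theta: np.ndarray) -> np.ndarray:
        e_tilde, ln_k = theta
        w = _pair_weights(n_fixed, np.array([e_tilde]))
        e_model = _apparent_matrix(
            n_fixed, math.exp(ln_k), w, basis, total, x_d, prox
        )[:, 0]
        return e_model - e_meas

    theta0 = np.array([start.e_tilde, math.log(start.assoc_const)])
    res = optimize.least_squares(
        residuals,
        theta0,
        bounds=([1e-6, -np.inf], [1 - 1e-6, np.inf]),
        x_scale="jac",
        method="trf",
    )
    if not res.success:
        raise NonConvergenceError(
            f"least-squares refinement failed: {res.message}", grid_best=start
        )

    e_hat = float(res.x[0])
    k_hat = math.exp(float(res.x[1]))
    ssr = float(np.sum(res.fun**2))
    refined_mse = ssr / n_pts
    dof = max(n_pts - 2, 1)
    sigma2 = ssr / dof
    # Jacobian wrt (E~, K): column for ln K rescales by 1/K.
    jac = res.jac.copy()
    jac[:, 1] /= k_hat
    jtj = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.inf, np.inf])
    tq = stats.t.ppf(0.975, dof)
    e_ci = (e_hat - tq * se[0], e_hat + tq * se[0])
    k_lo, k_hi = k_hat - tq * se[1], k_hat + tq * se[1]
    wide = bool(not np.isfinite(k_lo) or k_lo <= 0)
    kdiss_hat = 1.0 / k_hat
    kdiss_ci = (1.0 / k_hi if k_hi > 0 else 0.0, np.inf if wide else 1.0 / k_lo)

    ctx = ThermoContext(temperature=temperature)
    dg = delta_g(kdiss_hat, ctx)
    dg_ci = (
        delta_g(kdiss_ci[0], ctx) if kdiss_ci[0] > 0 else -np.inf,
        delta_g(kdiss_ci[1], ctx) if np.isfinite(kdiss_ci[1]) else np.inf,
    )

    return FitResult(
        mse_by_n=dict(mse_by_n) if mse_by_n is not None else {n_fixed: refined_mse},
        best_n=n_fixed,
        classification=classification,
        e_tilde=e_hat,
        e_tilde_ci=e_ci,
        assoc_const=k_hat,
        kdiss=kdiss_hat,
        kdiss_ci=kdiss_ci,
        delta_g=dg,
        delta_g_ci=dg_ci,
        refined_mse=refined_mse,
        n_points=n_pts,
        n_experiments=data.n_experiments,
        condition=data.condition,
        temperature=temperature,
        wide_kdiss_ci=wide,
    )


def fit_oligomer_model(
    data: MeasurementSet,
    proximity: Optional[ProximityTable] = None,
    grid: ParameterGrid = ParameterGrid(),
    n_values: Iterable[int] = range(2, 7),
    rel_tol: float = 0.02,
    temperature: float = 298.15,
) -> FitResult:
    """Full pipeline: grid MSE profile, order selection, NLLS refinement."""
    profile = mse_profile(data, proximity, grid, n_values)
    mse_by_n = {n: g.mse for n, g in profile.items()}
    best_n, classification = select_order(mse_by_n, rel_tol)
    return refine_fit(
        data,
        proximity,
        best_n,
        profile[best_n],
        mse_by_n=mse_by_n,
        classification=classification,
        temperature=temperature,
    )


def oligo_fraction_curve(
    fit: FitResult,
    data: MeasurementSet,
    proximity: Optional[ProximityTable] = None,
    conc_grid: Optional[np.ndarray] = None,
    n_bins: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Oligomeric-fraction curve with a binned data overlay.

    Returns ``(curve, bins)``: the theoretical ``f_oligo`` vs total density
    from the fitted model, and per-point apparent fractions (inverted from
    each region's efficiency under the fitted model) binned on a log-spaced
    density grid as mean +/- SEM.
    """
    model = OligomerModel(fit.best_n, fit.e_tilde, fit.assoc_const)
    total = data.total
    if conc_grid is None:
        conc_grid = np.logspace(
            np.log10(max(total.min(), 1e-2)), np.log10(total.max()), 100
        )
    conc_grid = np.asarray(conc_grid, dtype=float)
    m = monomer_concentration(conc_grid, model.n, model.assoc_const)
    f_theory = np.where(
        conc_grid > 0,
        model.n * model.assoc_const * m**model.n / np.maximum(conc_grid, 1e-300),
        0.0,
    )
    curve = pd.DataFrame({"total_conc": conc_grid, "f_oligo": f_theory})

    # apparent per-point fraction: E = f*s + (1-f)*p  =>  f = (E-p)/(s-p)
    s_full = _binomial_basis(model.n, data.donor_fraction, data.acceptor_fraction) @ _pair_weights(
        model.n, model.intrinsic_fret
    )
    s_full = s_full / (model.n * data.donor_fraction)
    p = _prox_per_point(data, proximity)
    denom = s_full - p
    f_app = np.where(np.abs(denom) > 1e-12, (data.efficiency - p) / denom, np.nan)
    f_app = np.clip(f_app, 0.0, 1.0)

    edges = np.logspace(np.log10(max(total.min(), 1e-2)), np.log10(total.max()), n_bins + 1)
    idx = np.clip(np.digitize(total, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = (idx == b) & np.isfinite(f_app)
        if sel.sum() == 0:
            continue
        vals = f_app[sel]
        rows.append(
            {
                "bin_center": math.sqrt(edges[b] * edges[b + 1]),
                "bin_mean": float(vals.mean()),
                "bin_sem": float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "n": int(sel.sum()),
            }
        )
    return curve, pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchComparison:
    """Welch's t-test between two fitted dissociation constants."""

    t_stat: float
    df: float
    p_value: float
    p_corrected: float
    significant: bool


def compare_kdiss(
    fit_a: FitResult,
    fit_b: FitResult,
    m_comparisons: int = 1,
    alpha: float = 0.05,
) -> WelchComparison:
    """Welch's t-test on two Kdiss estimates with Bonferroni correction.

    Standard errors are recovered from each fit's 95% confidence interval
    (half-width divided by the t quantile at the condition's replicate
    degrees of freedom, replicates being independent experiments); the
    Welch statistic and Welch-Satterthwaite degrees of freedom follow, and
    the two-sided p-value is multiplied by ``m_comparisons`` (capped at 1).
    """
    ses, dfs, ks = [], [], []
    for f in (fit_a, fit_b):
        if f.n_experiments is None or f.n_experiments < 2:
            raise ValueError(
                "compare_kdiss needs the number of independent experiments "
                "(>= 2) for each condition to set the degrees of freedom"
            )
        lo, hi = f.kdiss_ci
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("cannot compare fits with unbounded Kdiss intervals")
        df_i = f.n_experiments - 1
        se = (hi - lo) / 2.0 / stats.t.ppf(0.975, df_i)
        ses.append(se)
        dfs.append(df_i)
        ks.append(f.kdiss)
    v_a, v_b = ses[0] ** 2, ses[1] ** 2
    denom = math.sqrt(v_a + v_b)
    if denom == 0:
        t_stat, df_w = 0.0, float(sum(dfs))
        p = 1.0
    else:
        t_stat = (ks[0] - ks[1]) / denom
        df_w = (v_a + v_b) ** 2 / (v_a**2 / dfs[0] + v_b**2 / dfs[1])
        p = 2.0 * stats.t.sf(abs(t_stat), df_w)
    p_corr = min(1.0, p * m_comparisons)
    return WelchComparison(
        t_stat=float(t_stat),
        df=float(df_w),
        p_value=float(p),
        p_corrected=float(p_corr),
        significant=bool(p_corr < alpha),
    )


@dataclass(frozen=True)
class LinearityResult:
    """Outcome of the FRET-vs-acceptor-fraction linearity diagnostic."""

    bins: pd.DataFrame
    slope: float
    f_stat: float
    p_value: float
    verdict: str
    n_points: int


def fret_vs_acceptor_fraction(
    data: MeasurementSet,
    min_total_conc: float = 100.0,
    n_bins: int = 12,
    alpha: float = 0.05,
) -> LinearityResult:
    """Linearity diagnostic of mean FRET vs mean acceptor fraction.

    At high receptor density (``[T] > min_total_conc``, where the
    oligomeric fraction is near saturation) a dimer population gives an
    apparent efficiency linear in the acceptor fraction, ``E = E~ x_A``,
    whereas clusters give a convex dependence.  Regions passing the density
    filter are binned by acceptor fraction; the binned means are fitted by
    a through-origin line and by a through-origin quadratic, and an F-test
    at level ``alpha`` decides whether the quadratic term is warranted.

    Requires data acquired at two or more donor:acceptor transfection
    ratios, otherwise the acceptor fraction does not span a usable range.
    """
    if "ratio" in data.data.columns:
        n_ratios = data.data["ratio"].nunique()
    else:
        n_ratios = None
    mask = data.total > min_total_conc
    if mask.sum() == 0:
        raise ValueError(
            f"no regions exceed the density filter of {min_total_conc} receptors/um^2"
        )
    x_a = data.acceptor_fraction[mask]
    e = data.efficiency[mask]
    if n_ratios is not None:
        if n_ratios < 2:
            raise InsufficientDesignError(
                "linearity analysis needs >= 2 donor:acceptor ratios"
            )
    elif x_a.max() - x_a.min() < 0.15:
        raise InsufficientDesignError(
            "acceptor fractions span too narrow a range; the design appears "
            "to contain a single donor:acceptor ratio"
        )

    edges = np.linspace(x_a.min(), x_a.max(), n_bins + 1)
    idx = np.clip(np.digitize(x_a, edges) - 1, 0, n_bins - 1)
    xs, ys, ns = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 3:
            continue
        xs.append(float(x_a[sel].mean()))
        ys.append(float(e[sel].mean()))
        ns.append(int(sel.sum()))
    xs_a, ys_a = np.array(xs), np.array(ys)
    if len(xs_a) < 4:
        raise InsufficientDesignError(
            "too few populated acceptor-fraction bins for the linearity test"
        )
    bins = pd.DataFrame({"mean_x_a": xs_a, "mean_fret": ys_a, "n": ns})

    # through-origin linear vs through-origin quadratic, F-test on bin means
    slope = float(np.sum(xs_a * ys_a) / np.sum(xs_a**2))
    rss1 = float(np.sum((ys_a - slope * xs_a) ** 2))
    design = np.column_stack([xs_a, xs_a**2])
    coef, *_ = np.linalg.lstsq(design, ys_a, rcond=None)
    rss2 = float(np.sum((ys_a - design @ coef) ** 2))
    df2 = len(xs_a) - 2
    if rss2 <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (rss1 - rss2) / (rss2 / df2)
        p = float(stats.f.sf(f_stat, 1, df2))
    verdict = "nonlinear (cluster-consistent)" if p < alpha else "linear (dimer-consistent)"
    return LinearityResult(
        bins=bins,
        slope=slope,
        f_stat=float(f_stat),
        p_value=p,
        verdict=verdict,
        n_points=int(mask.sum()),
    )
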