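"""Initial-rate extraction and global fitting of photo-oxidation curves.

The measurable of the planar-bilayer experiment is the boundary potential
contributed by the dipolar target; under illumination it decays as the target
is oxidised.  The initial oxidation rate is the normalised initial slope,
``R = |d phi/dt|_{t=0} / phi_ads``.  Curves of 1/R versus adsorption
potential, recorded for both leaflet configurations (cis/trans) and several
photosensitizer densities, are fitted *globally*: some kinetic constants are
shared across every curve (``k_w``, ``k_w0``, ``k_to`` and the
invisible-target potential ``alpha*S_0``), some are shared only within one
photosensitizer (``k_gen``, ``k_so``), and the inter-layer transfer rates are
fixed from membrane permeability.  The model prediction is always the exact
3x3 steady-state solve of :mod:`sokinetics.model`, never the closed-form
curve.

The optimiser works in log10 parameter space (the constants span ~18 decades)
with a seeded multi-start to avoid local minima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import RateConstants, inverse_rate_curve

__all__ = [
    "RateDataset",
    "PotentialTrace",
    "InitialRate",
    "FitSpec",
    "FitResult",
    "extract_initial_rate",
    "global_fit",
    "bootstrap_uncertainty",
    "predict_inverse_rate",
    "DEFAULT_FIT_SPEC",
]

_GLOBAL_NAMES = ("k_w", "k_w0", "alpha_s0", "k_to")
_LOCAL_NAMES = ("k_gen", "k_so")


@dataclass(frozen=True)
class RateDataset:
    """One rate-vs-potential curve for a single (side, PS density) condition.

    ``phi_ads`` in volts, ``rate`` in s^-1, ``ps_density`` in molecules m^-2.
    """

    phi_ads: np.ndarray
    rate: np.ndarray
    side: str
    ps_label: str
    ps_density: float
    rate_se: np.ndarray | None = None

    def __post_init__(self):
        phi = np.asarray(self.phi_ads, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "phi_ads", phi)
        object.__setattr__(self, "rate", rate)
        if self.side not in ("cis", "trans"):
            raise ValueError(f"side must be cis|trans, got {self.side!r}")
        if phi.shape != rate.shape or phi.ndim != 1:
            raise ValueError("phi_ads and rate must be 1-D arrays of equal length")
        if np.any(phi <= 0) or np.any(rate <= 0):
            raise ValueError("phi_ads and rate must be strictly positive")
        if self.ps_density <= 0:
            raise ValueError("ps_density must be > 0")
        if self.rate_se is not None:
            object.__setattr__(self, "rate_se", np.asarray(self.rate_se, dtype=float))

    def __len__(self):
        return self.phi_ads.size


@dataclass(frozen=True)
class PotentialTrace:
    """A boundary-potential time trace around a light-on event.

    ``phi_ads`` is the pre-illumination plateau used for normalisation.
    """

    time: np.ndarray
    phi_b: np.ndarray
    phi_ads: float
    light_on_time: float = 0.0
    light: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.phi_b, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "phi_b", p)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("time and phi_b must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phi_ads <= 0:
            raise ValueError("phi_ads must be > 0")
        if self.light is not None:
            object.__setattr__(self, "light", np.asarray(self.light, dtype=float))


@dataclass(frozen=True)
class InitialRate:
    """Initial oxidation rate with its standard error and fit window size."""

    rate: float
    se: float
    n_points: int
    low_confidence: bool


def extract_initial_rate(
    trace: PotentialTrace, window_fraction: float = 0.1
) -> InitialRate:
    """Initial oxidation rate from the normalised initial slope of a trace.

    A straight line is fitted over the initial window after light-on; the
    window holds the samples within the first 10% of the total decay
    amplitude, or the first ``window_fraction`` of the post-light-on samples,
    whichever is smaller (never fewer than 5 points).  The slope's sampling
    standard error is propagated; if the slope is not resolved from zero at
    2 sigma the result is flagged low-confidence.
    """
    mask = trace.time >= trace.light_on_time
    t = trace.time[mask]
    p = trace.phi_b[mask]
    if t.size < 5:
        raise ValueError("need at least 5 samples after light-on")
    amplitude = p[0] - np.min(p)
    if amplitude > 0:
        within = p >= p[0] - 0.1 * amplitude
        # contiguous leading run only
        stop = np.argmin(within) if not within.all() else within.size
        n_amp = max(int(stop), 2)
    else:
        n_amp = t.size
    n_frac = max(int(math.ceil(window_fraction * t.size)), 2)
    n = max(min(n_amp, n_frac), 5)
    n = min(n, t.size)
    tw, pw = t[:n] - t[0], p[:n]
    coef, cov = np.polyfit(tw, pw, 1, cov=True)
    slope = float(coef[0])
    se = float(math.sqrt(max(cov[0, 0], 0.0)))
    rate = abs(slope) / trace.phi_ads
    return InitialRate(
        rate=rate,
        se=se / trace.phi_ads,
        n_points=n,
        low_confidence=abs(slope) < 2.0 * se,
    )


# --- global fit -------------------------------------------------------------

@dataclass(frozen=True)
class FitSpec:
    """Parameter architecture of the global fit.

    ``free_global`` are shared by every dataset; ``free_local`` are shared
    only among datasets with the same photosensitizer label; ``fixed`` are
    held constant.  Bounds are in native units; the optimiser works in log10.
    """

    free_global: tuple[str, ...] = _GLOBAL_NAMES
    free_local: tuple[str, ...] = _LOCAL_NAMES
    fixed: dict = field(
        default_factory=lambda: {
            "k_ctm": 2.4e8,
            "k_mct": 5.5e7,
            "alpha": 4.65e-19,
            "k_pso": 0.0,
        }
    )
    bounds: dict = field(
        default_factory=lambda: {
            "k_w": (5.0e4, 5.0e10),
            "k_w0": (2.9e4, 2.9e10),
            "alpha_s0": (1.0e-3, 0.3),        # V
            "k_to": (1.0e-13, 1.0e-7),        # m^2 s^-1, one-sided in practice
            "k_gen": (1.0e-3, 1.0e3),
            "k_so": (3.0e-13, 3.0e-7),
        }
    )
    initial: dict = field(
        default_factory=lambda: {
            "k_w": 5.0e7,
            "k_w0": 2.9e7,
            "alpha_s0": 0.02,
            "k_to": 6.0e-10,
            "k_gen": 1.0,
            "k_so": 3.0e-10,
        }
    )
    weight_mode: str = "on_inverse_rate"
    n_starts: int = 16
    reg_strength: float = 0.3
    reg_params: tuple[str, ...] = ("k_w", "k_w0", "k_to")
    """Ridge anchoring.  The rate curves determine only combinations of the
    constants — an exact flat ridge runs through parameter space (scaling
    k_gen, k_so with k_ctm+k_w while k_to scales inversely leaves every
    curve unchanged) — so individual constants require an external scale.
    ``reg_params`` are tethered to their initial values by a log-space
    Tikhonov penalty of weight ``reg_strength`` relative to the rms rate
    signal: the membrane loss rates (whose magnitude follows from the
    permeability-derived dwell time) and the target-oxidation constant
    (reference scale: k_to ~ k_so).  The quantities the experiment is
    designed to measure — k_gen, k_so and the invisible-target potential —
    are never penalised.  Set reg_strength to 0 for a pure (ridge-ambiguous)
    least squares."""

    def __post_init__(self):
        overlap = (
            set(self.free_global) & set(self.free_local)
            | set(self.free_global) & set(self.fixed)
            | set(self.free_local) & set(self.fixed)
        )
        if overlap:
            raise ValueError(f"parameters in two categories: {sorted(overlap)}")
        if self.weight_mode not in ("on_inverse_rate", "on_rate"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


DEFAULT_FIT_SPEC = FitSpec()


@dataclass
class FitResult:
    """Outcome of a global fit: estimates, uncertainties, and diagnostics.

    ``params`` maps parameter names (local ones suffixed ``:label``) to
    estimates in native units; ``stderr`` holds linearised covariance-based
    standard errors on the same scale; ``bound_flags`` marks parameters that
    ended within 1% (log scale) of a bound; for a flat ``k_to`` profile the
    one-sided ``k_to_lower_bound`` is reported instead of a two-sided error.
    """

    params: dict
    stderr: dict
    fixed: dict
    free_global: tuple
    free_local: tuple
    labels: tuple
    cost: float
    n_points: int
    residuals: list
    diagnostics: dict
    bound_flags: dict
    spec: FitSpec
    seed: int | None = None
    k_to_lower_bound: float | None = None
    bootstrap_halfwidths: dict | None = None

    def value(self, name: str, label: str | None = None) -> float:
        key = f"{name}:{label}" if label is not None and f"{name}:{label}" in self.params else name
        if key in self.params:
            return self.params[key]
        if name in self.fixed:
            return self.fixed[name]
        raise KeyError(name)

    def rate_constants(self, label: str) -> RateConstants:
        """Assemble the fitted kinetic constants for one photosensitizer."""
        return RateConstants(
            k_gen=self.value("k_gen", label),
            k_so=self.value("k_so", label),
            k_to=self.value("k_to", label),
            k_ctm=self.value("k_ctm", label),
            k_mct=self.value("k_mct", label),
            k_w=self.value("k_w", label),
            k_w0=self.value("k_w0", label),
            k_pso=self.value("k_pso", label),
        )

    @property
    def alpha_s0(self) -> float:
        return self.value("alpha_s0")

    @property
    def s0(self) -> float:
        return self.alpha_s0 / self.fixed["alpha"]


def _param_layout(spec: FitSpec, labels):
    names = list(spec.free_global)
    for label in labels:
        names += [f"{p}:{label}" for p in spec.free_local]
    return names


def _bounds_for(spec: FitSpec, name: str):
    base = name.split(":", 1)[0]
    return spec.bounds[base]


def _initial_for(spec: FitSpec, name: str):
    base = name.split(":", 1)[0]
    return spec.initial[base]


def _make_residual_fn(
    datasets, spec: FitSpec, names, x0_reg=None, w_reg=0.0, reg_exclude=()
):
    alpha = spec.fixed["alpha"]
    idx = {n: i for i, n in enumerate(names)}
    inv_data = [1.0 / ds.rate for ds in datasets]
    weights = [ds.rate**2 for ds in datasets]

    def get(x, name, label):
        key = f"{name}:{label}"
        if key in idx:
            return 10.0 ** x[idx[key]]
        if name in idx:
            return 10.0 ** x[idx[name]]
        return spec.fixed[name]

    def residual(x):
        out = []
        s0 = get(x, "alpha_s0", None) / alpha
        for k, ds in enumerate(datasets):
            rc = RateConstants(
                k_gen=get(x, "k_gen", ds.ps_label),
                k_so=get(x, "k_so", ds.ps_label),
                k_to=get(x, "k_to", ds.ps_label),
                k_ctm=spec.fixed["k_ctm"],
                k_mct=spec.fixed["k_mct"],
                k_w=get(x, "k_w", ds.ps_label),
                k_w0=get(x, "k_w0", ds.ps_label),
                k_pso=spec.fixed["k_pso"],
            )
            inv_model = inverse_rate_curve(
                rc, ds.side, ds.ps_density, ds.phi_ads, s0, alpha
            )
            if spec.weight_mode == "on_inverse_rate":
                out.append((inv_model - inv_data[k]) * weights[k])
            else:
                out.append(1.0 / inv_model - ds.rate)
        if w_reg > 0.0:
            x = np.asarray(x)
            out.append(w_reg * (x[reg_idx] - x0_reg[reg_idx]))
        return np.concatenate(out)

    reg_idx = np.array(
        [
            i
            for i, n in enumerate(names)
            if n.split(":", 1)[0] in spec.reg_params and n not in reg_exclude
        ],
        dtype=int,
    )
    return residual


def _cost_with_fixed(residual, x_start, i, logk, lo, hi):
    """Re-optimise all parameters but ``i`` (held at ``logk``); return cost."""
    free = [j for j in range(len(x_start)) if j != i]

    def res(xf):
        x = np.empty(len(x_start))
        x[free] = xf
        x[i] = logk
        return residual(x)

    sol = least_squares(
        res, x_start[free], bounds=(lo[free], hi[free]), method="trf",
        x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=1500,
    )
    return sol.cost


def global_fit(
    datasets, spec: FitSpec = DEFAULT_FIT_SPEC, seed: int | None = None
) -> "FitResult":
    """Globally fit the kinetic model to a set of rate-vs-potential curves.

    Minimises weighted squared residuals of 1/R (the presentation in which
    the curves are analysed; weights proportional to R^2) with the shared /
    per-photosensitizer parameter partition of ``spec``.  ``spec.n_starts``
    seeded starts are drawn log-uniformly within the bounds (the first start
    is ``spec.initial``); the best converged start wins.

    Identifiability requires the cis/trans contrast: without it (or with too
    few curves) the jacobian at the optimum is rank-deficient, which is
    reported in ``diagnostics`` rather than silently returning a minimum.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to fit")
    labels = tuple(sorted({ds.ps_label for ds in datasets}))
    sides_by_label = {
        label: {ds.side for ds in datasets if ds.ps_label == label} for label in labels
    }
    has_contrast = any(len(s) == 2 for s in sides_by_label.values())
    if not has_contrast:
        warnings.warn(
            "no photosensitizer has both cis and trans curves; the invisible-"
            "target density and quenching constants are not jointly identifiable",
            stacklevel=2,
        )

    names = _param_layout(spec, labels)
    lo = np.array([math.log10(_bounds_for(spec, n)[0]) for n in names])
    hi = np.array([math.log10(_bounds_for(spec, n)[1]) for n in names])
    x0_init = np.array([math.log10(_initial_for(spec, n)) for n in names])
    n_pts = sum(len(ds) for ds in datasets)
    data_scale2 = float(sum(np.sum(ds.rate**2) for ds in datasets))
    w_reg = spec.reg_strength * math.sqrt(data_scale2 / n_pts)
    residual = _make_residual_fn(datasets, spec, names, x0_init, w_reg)

    rng = np.random.default_rng(seed)
    starts = [np.clip(x0_init, lo, hi)]
    for _ in range(max(spec.n_starts - 1, 0)):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    start_costs = []
    solutions = []
    for x0 in starts:
        try:
            sol = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
                max_nfev=4000,
            )
        except Exception:  # a start may wander into a singular corner
            continue
        start_costs.append(sol.cost)
        solutions.append(sol)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    # The optimum can be a flat ridge (the curves constrain only parameter
    # combinations, not every constant individually).  All starts whose fit
    # is statistically indistinguishable from the best (delta chi^2 <= 1,
    # with a machine-level floor for exact data) sample that ridge.  Among
    # them the reported estimate is the solution closest (log10 Euclidean)
    # to the configured initial values — the nonlinear analogue of the
    # minimum-norm solution of rank-deficient least squares, with the
    # initial values acting as the physically motivated reference scale.
    # The ridge extent across the indistinguishable set is reported so the
    # flat directions are visible to the caller.
    dof = max(n_pts - len(names), 1)
    s2 = 2.0 * best.cost / dof
    thresh = max(s2, 1e-18 * data_scale2)
    near_sols = [s for s in solutions if 2.0 * (s.cost - best.cost) <= thresh]
    near = np.array([s.x for s in near_sols])
    ridge_extent = {
        n: float(near[:, i].max() - near[:, i].min()) for i, n in enumerate(names)
    }
    best = min(near_sols, key=lambda s: float(np.sum((s.x - x0_init) ** 2)))

    x = best.x
    params = {n: 10.0 ** x[i] for i, n in enumerate(names)}

    # linearised covariance in log10 space
    jac = best.jac
    jtj = jac.T @ jac
    sv = np.linalg.svd(jtj, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    try:
        cov_log = np.linalg.inv(jtj) * s2
        sig_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    except np.linalg.LinAlgError:
        sig_log = np.full(len(names), math.nan)
    stderr = {
        n: params[n] * math.log(10.0) * sig_log[i] for i, n in enumerate(names)
    }

    bound_flags = {}
    for i, n in enumerate(names):
        span = hi[i] - lo[i]
        bound_flags[n] = bool(
            x[i] - lo[i] < 0.01 * span or hi[i] - x[i] < 0.01 * span
        )

    residuals = []
    offset = 0
    full_res = residual(x)
    for ds in datasets:
        residuals.append(full_res[offset:offset + len(ds)])
        offset += len(ds)

    result = FitResult(
        params=params,
        stderr=stderr,
        fixed=dict(spec.fixed),
        free_global=spec.free_global,
        free_local=spec.free_local,
        labels=labels,
        cost=float(best.cost),
        n_points=n_pts,
        residuals=residuals,
        diagnostics={
            "phi_max": float(max(np.max(ds.phi_ads) for ds in datasets)),
            "jacobian_condition": cond,
            "rank_deficient": cond > 1e10 or not has_contrast,
            "n_starts": len(starts),
            "n_starts_converged": len(start_costs),
            "n_near_optimal": int(near.shape[0]),
            "ridge_extent_log10": ridge_extent,
            "start_costs": sorted(start_costs),
        },
        bound_flags=bound_flags,
        spec=spec,
        seed=seed,
    )

    # One-sided report for k_to (mirrors a ">= value" entry): when oxidation
    # of the T moiety is fast compared with the middle-layer losses, the
    # curves bound k_to only from below, and the fitted value is dragged far
    # above its reference anchor.  In that regime a symmetric error is
    # meaningless; report instead the profile lower bound — the k_to below
    # which the (otherwise anchored) fit degrades by one chi-square unit.
    if "k_to" in names and spec.reg_strength > 0 and "k_to" in spec.reg_params:
        i = names.index("k_to")
        one_sided = (x[i] - x0_init[i] > 0.5) or bound_flags["k_to"]
        result.diagnostics["k_to_one_sided"] = bool(one_sided)
        if one_sided:
            res_probe = _make_residual_fn(
                datasets, spec, names, x0_init, w_reg, reg_exclude=("k_to",)
            )
            cost0 = 0.5 * float(np.sum(res_probe(x) ** 2))
            unit = 0.5 * max(s2, 1e-12 * data_scale2)
            result.k_to_lower_bound = _profile_lower_bound(
                res_probe, x, lo, hi, i, cost0, unit
            )
    return result


def _profile_lower_bound(residual, x_best, lo, hi, i, cost_best, unit):
    """Largest k_to below the estimate at which the profiled loss has risen
    by one chi-square unit, scanned on a 0.25-decade grid."""
    target = cost_best + unit
    logk = x_best[i]
    prev = logk
    for _ in range(24):
        logk -= 0.25
        if logk < lo[i]:
            return 10.0 ** lo[i]
        if _cost_with_fixed(residual, x_best, i, logk, lo, hi) > target:
            return 10.0 ** prev
        prev = logk
    return 10.0 ** prev


def bootstrap_uncertainty(
    datasets,
    spec: FitSpec = DEFAULT_FIT_SPEC,
    n_boot: int = 200,
    seed: int | None = None,
    fit: FitResult | None = None,
) -> dict:
    """Residual-resampling bootstrap half-widths for the fitted parameters.

    Resamples the inverse-rate residuals of the converged fit with
    replacement, rebuilds synthetic datasets, refits each (single start from
    the point estimate), and reports the central 68% half-width per
    parameter.  Deterministic for a given seed.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for a meaningful interval")
    datasets = list(datasets)
    if fit is None:
        fit = global_fit(datasets, spec, seed=seed)
    labels = fit.labels
    names = _param_layout(spec, labels)
    alpha = spec.fixed["alpha"]

    inv_model = []
    for ds in datasets:
        rc = fit.rate_constants(ds.ps_label)
        inv_model.append(
            inverse_rate_curve(rc, ds.side, ds.ps_density, ds.phi_ads, fit.s0, alpha)
        )
    # relative residuals are homoscedastic across datasets whose rates span
    # orders of magnitude (the noise on rates is multiplicative)
    resid = [1.0 / ds.rate / m - 1.0 for ds, m in zip(datasets, inv_model)]
    all_resid = np.concatenate(resid)

    lo = np.array([math.log10(_bounds_for(spec, n)[0]) for n in names])
    hi = np.array([math.log10(_bounds_for(spec, n)[1]) for n in names])
    x_best = np.array([math.log10(fit.params[n]) for n in names])
    x0_init = np.array([math.log10(_initial_for(spec, n)) for n in names])
    n_pts = sum(len(ds) for ds in datasets)
    data_scale2 = float(sum(np.sum(ds.rate**2) for ds in datasets))
    w_reg = spec.reg_strength * math.sqrt(data_scale2 / n_pts)

    rng = np.random.default_rng(seed)
    draws = {n: [] for n in names}
    for _ in range(n_boot):
        e = rng.choice(all_resid, size=all_resid.size, replace=True)
        offset = 0
        boot_sets = []
        for ds, m in zip(datasets, inv_model):
            inv_new = m * (1.0 + e[offset:offset + len(ds)])
            offset += len(ds)
            inv_new = np.clip(inv_new, 1e-300, None)
            boot_sets.append(
                RateDataset(
                    phi_ads=ds.phi_ads, rate=1.0 / inv_new, side=ds.side,
                    ps_label=ds.ps_label, ps_density=ds.ps_density,
                )
            )
        residual = _make_residual_fn(boot_sets, spec, names, x0_init, w_reg)
        sol = least_squares(
            residual, x_best, bounds=(lo, hi), method="trf", x_scale="jac",
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        for i, n in enumerate(names):
            draws[n].append(10.0 ** sol.x[i])

    halfwidths = {}
    for n in names:
        q16, q84 = np.quantile(draws[n], [0.16, 0.84])
        halfwidths[n] = float((q84 - q16) / 2.0)
    if fit is not None:
        fit.bootstrap_halfwidths = halfwidths
    return halfwidths


def predict_inverse_rate(
    fit: FitResult, phi_grid, side: str, ps_label: str, ps_density: float
) -> np.ndarray:
    """Model-predicted 1/R on a potential grid for one configuration.

    Warns when the grid extends beyond twice the largest potential seen in
    the fitted data (extrapolation)."""
    phi_grid = np.asarray(phi_grid, dtype=float)
    rc = fit.rate_constants(ps_label)
    alpha = fit.fixed["alpha"]
    fitted_max = fit.diagnostics.get("phi_max")
    if fitted_max and np.max(phi_grid) > 2.0 * fitted_max:
        warnings.warn("prediction grid extrapolates beyond 2x the fitted "
                      "potential range", stacklevel=2)
    return inverse_rate_curve(rc, side, ps_density, phi_grid, fit.s0, alpha)
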