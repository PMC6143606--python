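"""Three-layer kinetic model of singlet oxygen in a planar lipid bilayer.

The membrane is discretised into three layers: the *cis* leaflet carrying the
membrane-bound photosensitizer (PS), the hydrophobic *middle* layer, and the
opposite *trans* leaflet.  Singlet oxygen (SO) is generated photochemically in
the cis layer at a rate ``k_gen * PS``, hops between adjacent layers
(``k_ctm`` outward->middle, ``k_mct`` middle->outward), escapes or is quenched
at the interfaces (``k_w``) and in the core (``k_w0``), and reacts with a
dipolar target molecule that spans one leaflet and the core.  The target has
two SO-susceptible moieties:

* **T** — the dipole-carrying group sitting in the middle layer; its oxidation
  (rate constant ``k_to``) erases the molecule's contribution to the membrane
  dipole potential and is the observable of the experiment;
* **S** — the unsaturated chain in the adsorbing leaflet; it quenches SO
  (``k_so``) with no electrical signature, so it shields T without being seen.

The target may sit on the same leaflet as the PS (*cis* configuration) or on
the opposite one (*trans*).  Because SO born in the cis layer must first run
the S-quenching gauntlet in cis mode, the observed photo-oxidation rate obeys
``R_cis < R_trans`` whenever ``k_so > 0`` — the central qualitative prediction
of the model.

All quantities are SI internally: surface densities in molecules m^-2,
bimolecular surface rate constants in m^2 s^-1, first-order rates in s^-1,
potentials in V.  The measured adsorption potential is proportional to the
visible-target density, ``phi = alpha * T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Side",
    "RateConstants",
    "PhysicalConstants",
    "ExperimentConfig",
    "SOState",
    "ClosedFormCoefficients",
    "TimescaleReport",
    "NoSteadyStateError",
    "so_rhs",
    "steady_state_so",
    "oxidation_rate",
    "inverse_rate_curve",
    "rate_ratio",
    "closed_form_coefficients",
    "integrate_photobleaching",
    "derived_timescales",
    "transfer_rates_from_permeability",
    "ALPCS2",
    "ALPCS4",
    "DEFAULT_PHYSICAL",
]

Side = Literal["cis", "trans"]


class NoSteadyStateError(ValueError):
    """The frozen SO balance has no finite steady state (no loss, finite source)."""


def _check_nonnegative(obj, names):
    for name in names:
        if getattr(obj, name) < 0:
            raise ValueError(f"{name} must be >= 0, got {getattr(obj, name)!r}")


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the three-layer SO scheme.

    Parameters
    ----------
    k_gen : SO generation rate per PS molecule, m^2 s^-1.
    k_so : SO quenching by the S moiety, m^2 s^-1.
    k_to : oxidation of the T moiety by SO, m^2 s^-1.
    k_ctm : SO transfer, outer layer -> middle, s^-1.
    k_mct : SO transfer, middle -> one outer layer, s^-1.
    k_w : SO loss from an outer layer (escape to water + quenching), s^-1.
    k_w0 : SO quenching in the middle layer, s^-1.
    k_pso : SO quenching by the PS itself, m^2 s^-1 (0 in the standard regime).
    k_ads : target adsorption from solution, per unit aqueous conc. per s.
    k_des : target desorption back to solution, s^-1.
    """

    k_gen: float
    k_so: float
    k_to: float
    k_ctm: float
    k_mct: float
    k_w: float
    k_w0: float
    k_pso: float = 0.0
    k_ads: float = 0.0
    k_des: float = 0.0

    def __post_init__(self):
        _check_nonnegative(
            self,
            ("k_gen", "k_so", "k_to", "k_ctm", "k_mct", "k_w", "k_w0",
             "k_pso", "k_ads", "k_des"),
        )

    def replace(self, **kwargs) -> "RateConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants tying the kinetic scheme to measurable quantities.

    alpha : adsorption potential per unit visible-target density, V m^2.
    K_p : water/membrane oxygen partition coefficient (dimensionless).
    P_M : membrane permeability to (singlet) oxygen, m s^-1.
    D_aq : SO diffusion coefficient, m^2 s^-1.
    thickness : membrane thickness, m.
    tau_l_ref : reference SO lifetime used for the travel-span estimate, s.
    """

    alpha: float = 4.65e-19
    K_p: float = 4.4
    P_M: float = 0.80
    D_aq: float = 5.0e-9
    thickness: float = 4.0e-9
    tau_l_ref: float = 3.0e-6

    def __post_init__(self):
        for name in ("alpha", "K_p", "P_M", "D_aq", "thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_l_ref < 0:
            raise ValueError("tau_l_ref must be >= 0")


@dataclass(frozen=True)
class ExperimentConfig:
    """One membrane configuration: target side, PS density, target densities.

    ``t0`` is the pre-illumination ("visible") target density fixed by the
    adsorption equilibrium, ``s0`` the density of already-oxidised molecules
    that still quench SO but carry no dipole signal.  The total quenching
    density is ``t0 + s0`` under the initial-rate convention.
    """

    side: Side
    ps_density: float
    t0: float
    s0: float = 0.0
    target_aqueous: float | None = None

    def __post_init__(self):
        if self.side not in ("cis", "trans"):
            raise ValueError(f"side must be 'cis' or 'trans', got {self.side!r}")
        _check_nonnegative(self, ("ps_density", "t0", "s0"))


@dataclass(frozen=True)
class SOState:
    """SO surface concentrations in the three layers plus target densities."""

    o_c: float
    o_m: float
    o_t: float
    t_vis: float
    s_tot: float

    def __post_init__(self):
        _check_nonnegative(self, ("o_c", "o_m", "o_t", "t_vis", "s_tot"))


@dataclass(frozen=True)
class TimescaleReport:
    """Derived SO timescales (seconds; lengths in metres)."""

    tau_dw_sum: float      # membrane dwell time, 1/k_mct + 1/k_w
    tau_t: float           # diffusion travel time PS -> target, r^2/D
    tau_to: float          # reaction time with the target, 1/(k_so * density)
    delta_travel: float    # diffusion span during the SO lifetime, sqrt(D tau_l)
    tau_dw_simple: float   # crude dwell estimate, thickness^2/D


# --- right-hand sides -------------------------------------------------------

def so_rhs(state: SOState, rc: RateConstants, cfg: ExperimentConfig):
    """Time derivatives (d t_vis, d o_c, d o_m, d o_t) of the kinetic scheme.

    In cis mode the S-quenching term ``k_so * s_tot`` acts on the cis layer
    (where the PS also sits); in trans mode it acts on the trans layer.  The
    target supply term uses the adsorption/desorption pair when an aqueous
    concentration is configured.
    """
    t, oc, om, ot = state.t_vis, state.o_c, state.o_m, state.o_t
    s = state.s_tot
    ps = cfg.ps_density

    if cfg.target_aqueous is not None:
        supply = rc.k_ads * cfg.target_aqueous
    else:
        # equilibrium convention: source balances desorption at t_vis = t0
        supply = rc.k_des * cfg.t0

    dt = supply - rc.k_des * t - rc.k_to * t * om

    gen = rc.k_gen * ps
    out_loss = rc.k_pso * ps + rc.k_ctm + rc.k_w
    if cfg.side == "cis":
        doc = gen - rc.k_so * s * oc - out_loss * oc + rc.k_mct * om
        dot = rc.k_mct * om - (rc.k_ctm + rc.k_w) * ot
    else:
        doc = gen - out_loss * oc + rc.k_mct * om
        dot = -rc.k_so * s * ot + rc.k_mct * om - (rc.k_ctm + rc.k_w) * ot
    dom = rc.k_ctm * (oc + ot) - (2.0 * rc.k_mct + rc.k_w0) * om - rc.k_to * t * om
    return dt, doc, dom, dot


# --- steady state -----------------------------------------------------------

def _steady_matrix(rc: RateConstants, side: Side, ps: float, t: float, s: float):
    """3x3 loss matrix M and source b such that M @ (O_c, O_m, O_t) = b."""
    c_out = rc.k_ctm + rc.k_w
    a_c = rc.k_pso * ps + c_out + (rc.k_so * s if side == "cis" else 0.0)
    a_t = c_out + (rc.k_so * s if side == "trans" else 0.0)
    b_m = 2.0 * rc.k_mct + rc.k_w0 + rc.k_to * t
    m = np.array(
        [
            [a_c, -rc.k_mct, 0.0],
            [-rc.k_ctm, b_m, -rc.k_ctm],
            [0.0, -rc.k_mct, a_t],
        ]
    )
    b = np.array([rc.k_gen * ps, 0.0, 0.0])
    return m, b


def steady_state_so(
    rc: RateConstants,
    cfg: ExperimentConfig,
    t_fixed: float | None = None,
    s_fixed: float | None = None,
) -> SOState:
    """Exact steady state of the SO balance with frozen target densities.

    With T and S frozen the three SO equations are linear; the state is a
    direct 3x3 solve.  Defaults: ``t_fixed = cfg.t0``,
    ``s_fixed = cfg.t0 + cfg.s0`` (initial-rate convention).
    """
    t = cfg.t0 if t_fixed is None else t_fixed
    s = cfg.t0 + cfg.s0 if s_fixed is None else s_fixed
    if t < 0 or s < 0:
        raise ValueError("target densities must be >= 0")
    m, b = _steady_matrix(rc, cfg.side, cfg.ps_density, t, s)
    gen = b[0]
    if gen == 0.0:
        return SOState(0.0, 0.0, 0.0, t, s)
    try:
        o = np.linalg.solve(m, b)
    except np.linalg.LinAlgError as exc:
        raise NoSteadyStateError(
            "SO balance is singular: finite generation with no loss path"
        ) from exc
    if not np.all(np.isfinite(o)) or np.any(o < 0):
        raise NoSteadyStateError("SO balance has no non-negative steady state")
    return SOState(float(o[0]), float(o[1]), float(o[2]), t, s)


def oxidation_rate(rc: RateConstants, cfg: ExperimentConfig) -> float:
    """Initial photo-oxidation rate R = k_to * O_m at the frozen steady state.

    R is the magnitude of the initial slope of the relative adsorption
    potential under illumination.  Defined for ``t0 = 0`` as well (the rate of
    T loss per molecule), although the relative-potential normalisation that
    the measurement relies on is then degenerate.
    """
    state = steady_state_so(rc, cfg)
    return rc.k_to * state.o_m


def inverse_rate_curve(
    rc: RateConstants,
    side: Side,
    ps_density: float,
    phi: np.ndarray,
    s0: float,
    alpha: float,
) -> np.ndarray:
    """Vectorised 1/R over a grid of adsorption potentials ``phi`` (V).

    Batch 3x3 linear solves of the frozen steady state; used by the fitting
    and synthetic-data layers where the rate is evaluated on whole curves.
    """
    phi = np.asarray(phi, dtype=float)
    t0 = phi / alpha
    n = t0.size
    s = t0 + s0
    c_out = rc.k_ctm + rc.k_w
    a_c = rc.k_pso * ps_density + c_out + (rc.k_so * s if side == "cis" else 0.0)
    a_t = c_out + (rc.k_so * s if side == "trans" else 0.0)
    b_m = 2.0 * rc.k_mct + rc.k_w0 + rc.k_to * t0
    m = np.zeros((n, 3, 3))
    m[:, 0, 0] = a_c
    m[:, 0, 1] = -rc.k_mct
    m[:, 1, 0] = -rc.k_ctm
    m[:, 1, 1] = b_m
    m[:, 1, 2] = -rc.k_ctm
    m[:, 2, 1] = -rc.k_mct
    m[:, 2, 2] = a_t
    b = np.zeros((n, 3, 1))
    b[:, 0, 0] = rc.k_gen * ps_density
    o = np.linalg.solve(m, b)[..., 0]
    rate = rc.k_to * o[:, 1]
    return 1.0 / rate


def rate_ratio(rc: RateConstants, t0: float, s0: float) -> float:
    """Closed-form ratio R_cis / R_trans of the two configurations.

    ``(k_ctm + k_w) / (k_ctm + k_w + k_so (t0 + s0))`` — exactly the ratio of
    the two frozen steady states when PS self-quenching is off, and always
    < 1 for a finite quenching density.
    """
    if rc.k_pso != 0.0:
        raise ValueError("closed-form ratio assumes k_pso = 0")
    c_out = rc.k_ctm + rc.k_w
    return c_out / (c_out + rc.k_so * (t0 + s0))


# --- closed-form inverse-rate curve ----------------------------------------

@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Coefficients of the exact closed-form inverse-rate curve.

    ``1/R_cis = a1 phi^2 + a2 phi + a3`` with phi = alpha * t0 the adsorption
    potential, and ``1/R_trans = (1/R_cis) * b1 / (b2 + alpha*s0)`` with
    ``b2 = b1 + phi``.  Obtained by symbolic elimination of the frozen
    steady-state system, so the curve reproduces the 3x3 linear solve to
    machine precision.  ``interpretation_phi0`` records which reading of the
    ambiguous offset potential in the traditional coefficient notation the a2
    term corresponds to (here: half the invisible-target potential,
    ``alpha*s0/2``).
    """

    a1: float  # s V^-2
    a2: float  # s V^-1
    a3: float  # s
    b1: float  # V
    b2_offset: float  # V; b2(phi) = b1 + phi, stored without the phi part
    interpretation_phi0: str = "alpha_s0_half"

    def inverse_rate_cis(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self.a1 * phi**2 + self.a2 * phi + self.a3

    def inverse_rate_trans(self, phi, alpha_s0: float):
        phi = np.asarray(phi, dtype=float)
        return self.inverse_rate_cis(phi) * self.b1 / (self.b1 + phi + alpha_s0)


def closed_form_coefficients(
    rc: RateConstants, cfg: ExperimentConfig, phys: PhysicalConstants
) -> ClosedFormCoefficients:
    """Exact quadratic-in-phi coefficients of 1/R_cis for this configuration.

    Requires ``k_pso = 0`` (the regime in which the elimination was done) and
    a finite PS density and ``k_to`` (otherwise 1/R diverges).
    """
    if rc.k_pso != 0.0:
        raise ValueError("closed form derived for k_pso = 0")
    if cfg.ps_density == 0.0:
        raise ValueError("closed-form coefficients undefined at zero PS density")
    if rc.k_to == 0.0 or rc.k_gen == 0.0 or rc.k_ctm == 0.0:
        raise ValueError("closed form requires k_to, k_gen, k_ctm > 0")
    alpha = phys.alpha
    g = rc.k_gen * cfg.ps_density
    c_out = rc.k_ctm + rc.k_w
    # core first-order loss seen from the middle layer (t0-independent part)
    b0 = rc.k_w0 + rc.k_mct + rc.k_mct * rc.k_w / c_out
    a1 = rc.k_so / (rc.k_ctm * g * alpha**2)
    a2 = (rc.k_so * (b0 + cfg.s0 * rc.k_to) + c_out * rc.k_to) / (
        rc.k_ctm * rc.k_to * g * alpha
    )
    a3 = ((rc.k_so * cfg.s0 + c_out) * b0 - rc.k_ctm * rc.k_mct) / (
        rc.k_ctm * rc.k_to * g
    )
    b1 = alpha * c_out / rc.k_so if rc.k_so > 0 else math.inf
    return ClosedFormCoefficients(a1=a1, a2=a2, a3=a3, b1=b1, b2_offset=b1)


# --- time-course integration (QSSA) ----------------------------------------

def integrate_photobleaching(
    rc: RateConstants,
    cfg: ExperimentConfig,
    schedule: Sequence[tuple[bool | str, float]],
    n_per_segment: int = 200,
    rtol: float = 1e-8,
    t_start: float | None = None,
):
    """Integrate the visible-target density through an illumination schedule.

    SO equilibrates within tens of nanoseconds while the target bleaches over
    seconds to minutes, so the SO pool is treated quasi-statically: during
    illumination ``d t_vis/dt = supply - k_des t_vis - k_to t_vis O_m(t_vis)``
    with ``O_m`` recomputed from the frozen steady state at every evaluation
    (and ``s_tot`` tracking ``t_vis + s0``); in the dark ``O_m = 0`` and the
    target relaxes back to ``t0`` at rate ``k_des``.

    Parameters
    ----------
    schedule : sequence of (light, duration) segments; light may be a bool or
        one of the strings "on"/"off"; durations in seconds, > 0.
    t_start : initial visible-target density (defaults to the equilibrium
        density ``cfg.t0``; useful for relaxation-from-depletion runs).

    Returns
    -------
    t, phi_rel, light : arrays of sample times, relative potential
        ``t_vis/t0``, and the 0/1 illumination state.
    """
    if cfg.t0 <= 0:
        raise ValueError("integrate_photobleaching requires t0 > 0")
    if not schedule:
        raise ValueError("empty illumination schedule")
    if cfg.target_aqueous is not None:
        supply = rc.k_ads * cfg.target_aqueous
    else:
        supply = rc.k_des * cfg.t0

    def rhs_light(t, y):
        tv = max(y[0], 0.0)
        state = steady_state_so(rc, cfg, t_fixed=tv, s_fixed=tv + cfg.s0)
        return [supply - rc.k_des * tv - rc.k_to * tv * state.o_m]

    def rhs_dark(t, y):
        return [supply - rc.k_des * y[0]]

    y0 = cfg.t0 if t_start is None else float(t_start)
    if y0 < 0:
        raise ValueError("t_start must be >= 0")
    times = [np.array([0.0])]
    values = [np.array([y0])]
    lights = [np.array([0.0])]
    t_now, y_now = 0.0, y0
    for light, duration in schedule:
        if isinstance(light, str):
            if light not in ("on", "off"):
                raise ValueError(f"light must be 'on' or 'off', got {light!r}")
            light = light == "on"
        if duration <= 0:
            raise ValueError("schedule durations must be > 0")
        t_eval = np.linspace(t_now, t_now + duration, n_per_segment + 1)[1:]
        sol = solve_ivp(
            rhs_light if light else rhs_dark,
            (t_now, t_now + duration),
            [y_now],
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=cfg.t0 * 1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"QSSA integration failed: {sol.message}")
        times.append(sol.t)
        values.append(sol.y[0])
        lights.append(np.full_like(sol.t, 1.0 if light else 0.0))
        t_now = t_now + duration
        y_now = float(sol.y[0, -1])
    t = np.concatenate(times)
    phi_rel = np.concatenate(values) / cfg.t0
    light_arr = np.concatenate(lights)
    return t, phi_rel, light_arr


# --- derived timescales and transfer rates ----------------------------------

def derived_timescales(
    rc: RateConstants,
    phys: PhysicalConstants,
    ps_dt_distance: float,
    target_density: float,
) -> TimescaleReport:
    """Characteristic SO timescales implied by the fitted constants.

    Zero rate constants yield infinite timescales (reported as ``inf``).
    """
    if ps_dt_distance <= 0 or target_density <= 0:
        raise ValueError("distance and target density must be > 0")
    inv = lambda x: (1.0 / x) if x > 0 else math.inf
    return TimescaleReport(
        tau_dw_sum=inv(rc.k_mct) + inv(rc.k_w),
        tau_t=ps_dt_distance**2 / phys.D_aq,
        tau_to=inv(rc.k_so * target_density),
        delta_travel=math.sqrt(phys.D_aq * phys.tau_l_ref),
        tau_dw_simple=phys.thickness**2 / phys.D_aq,
    )


#: transfer rates pinned to the values used in the published fits
_PRINTED_K_CTM = 2.4e8
_PRINTED_K_MCT = 5.5e7


def transfer_rates_from_permeability(
    phys: PhysicalConstants, use_printed: bool = False
) -> tuple[float, float]:
    """Inter-layer transfer rates (k_ctm, k_mct) from membrane permeability.

    The permeability of a slab of thickness d is ``P_M = K_p D_M / d`` with
    ``D_M = d^2/(2 tau)`` the Einstein relation for the crossing time tau.
    Replacing the full thickness by the layer spacing d/3 and 1/tau by the
    hop rate gives ``k_ctm = 6 P_M / (K_p d)``, and detailed balance across
    the water/membrane partition gives ``k_mct = k_ctm / K_p``.

    With ``use_printed=True`` the pair is pinned to the rounded values used
    in the reference global fits (2.4e8, 5.5e7 s^-1); the direct formula with
    d = 4 nm, K_p = 4.4 yields ~2.7e8 s^-1, a known rounding-level mismatch.
    """
    if use_printed:
        return _PRINTED_K_CTM, _PRINTED_K_MCT
    k_ctm = 6.0 * phys.P_M / (phys.K_p * phys.thickness)
    return k_ctm, k_ctm / phys.K_p


# --- reference parameter sets -----------------------------------------------

DEFAULT_PHYSICAL = PhysicalConstants()

#: reference fit, disulfonated phthalocyanine (membrane-penetrating PS)
ALPCS2 = RateConstants(
    k_gen=2.4,
    k_so=6.0e-10,
    k_to=6.0e-10,
    k_ctm=_PRINTED_K_CTM,
    k_mct=_PRINTED_K_MCT,
    k_w=5.0e7,
    k_w0=2.9e7,
    k_des=5.0e-3,
)

#: reference fit, tetrasulfonated phthalocyanine (surface-bound PS)
ALPCS4 = ALPCS2.replace(k_gen=0.6, k_so=1.5e-10)
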