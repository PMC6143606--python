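"""Fluorescence correlation spectroscopy (FCS) calibration chain.

Converts fluorescence autocorrelation decays recorded on a horizontal planar
bilayer into lateral diffusion coefficients and membrane surface densities.
The chain is: fit the one-component 2D translational model
``G(tau) = 1 + 1/(N (1 + tau/tau_D))`` to a trace, calibrate the confocal
focus with a free-dye standard of known diffusion coefficient
(``omega_r^2 = 4 D tau``), then convert the membrane dye's residence time to
``D = omega_r^2 / (4 tau_D)`` and its particle number to a surface density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "FCSTrace",
    "FCSFitResult",
    "FocusCalibration",
    "DensityConversion",
    "DyeStandard",
    "FITC",
    "CY5",
    "NoSignalError",
    "autocorrelation_model",
    "fit_autocorrelation",
    "calibrate_focus",
    "focus_from_volume",
    "diffusion_from_residence",
    "density_conversions",
    "DEFAULT_CONVERSION",
]


class NoSignalError(ValueError):
    """The autocorrelation trace carries no decaying component to fit."""


@dataclass(frozen=True)
class FCSTrace:
    """Autocorrelation samples (lag in s, dimensionless G) with a label."""

    lag: np.ndarray
    g: np.ndarray
    label: str = ""

    def __post_init__(self):
        lag = np.asarray(self.lag, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lag", lag)
        object.__setattr__(self, "g", g)
        if lag.ndim != 1 or lag.shape != g.shape:
            raise ValueError("lag and g must be 1-D arrays of equal length")
        if np.any(np.diff(lag) <= 0):
            raise ValueError("lag values must be strictly increasing")


@dataclass(frozen=True)
class DyeStandard:
    """Calibration dye: known diffusion coefficient and measured focus time."""

    name: str
    d: float       # m^2 s^-1
    tau: float     # s
    s_param: float  # structural parameter omega_z / omega_r


#: fluorescein isothiocyanate in the 488 nm channel
FITC = DyeStandard("FITC", d=565e-12, tau=18e-6, s_param=5.0)
#: Cy5 in the red channel
CY5 = DyeStandard("Cy5", d=280e-12, tau=31.6e-6, s_param=8.0)


@dataclass(frozen=True)
class FocusCalibration:
    """Confocal focus geometry derived from a calibration standard."""

    omega_r: float   # lateral focus radius, m
    s_param: float   # omega_z / omega_r
    volume: float    # confocal volume, m^3
    standard: DyeStandard | None = None

    def __post_init__(self):
        if self.omega_r <= 0 or self.volume <= 0:
            raise ValueError("focus radius and volume must be > 0")
        if self.s_param <= 1:
            raise ValueError("structural parameter must exceed 1")


@dataclass(frozen=True)
class FCSFitResult:
    n_mol: float
    tau_d: float
    n_mol_se: float
    tau_d_se: float
    residual_lag1_autocorr: float
    """Lag-1 autocorrelation of the fit residuals: |value| well above
    ~2/sqrt(n) indicates structured misfit (e.g. the trace follows a
    different diffusion model)."""
    chi2_reduced: float


def autocorrelation_model(lag, n_mol: float, tau_d: float):
    """One-component 2D translational diffusion autocorrelation.

    ``G(tau) = 1 + 1/(N (1 + tau/tau_D))`` — amplitude 1/N at zero lag,
    half-amplitude at ``tau = tau_D``, decorrelating to 1.
    """
    if n_mol <= 0 or tau_d <= 0:
        raise ValueError("n_mol and tau_d must be > 0")
    lag = np.asarray(lag, dtype=float)
    return 1.0 + 1.0 / (n_mol * (1.0 + lag / tau_d))


def fit_autocorrelation(trace: FCSTrace, weights=None) -> FCSFitResult:
    """Weighted least-squares fit of the 2D model to an autocorrelation trace.

    Initial values come from the trace itself (amplitude -> N, half-decay
    lag -> tau_D).  Raises :class:`NoSignalError` for a flat trace.
    """
    lag, g = trace.lag, trace.g
    if lag.size < 10:
        raise ValueError("need at least 10 lag points to fit")
    amp0 = float(np.max(g) - 1.0)
    if amp0 < 1e-6:
        raise NoSignalError(f"trace {trace.label!r} is flat (G ~ 1 everywhere)")
    n0 = 1.0 / amp0
    half = 1.0 + amp0 / 2.0
    idx = np.argmin(np.abs(g - half))
    tau0 = float(lag[idx]) if lag[idx] > 0 else float(np.median(lag))

    params = lmfit.Parameters()
    params.add("n_mol", value=n0, min=1e-6)
    params.add("tau_d", value=tau0, min=float(lag[0]) * 1e-3)
    w = np.ones_like(g) if weights is None else np.asarray(weights, dtype=float)

    def residual(p):
        return (g - autocorrelation_model(lag, p["n_mol"].value, p["tau_d"].value)) * w

    out = lmfit.minimize(residual, params, method="least_squares")
    res = residual(out.params)
    r = res - res.mean()
    denom = float(np.dot(r, r))
    lag1 = float(np.dot(r[:-1], r[1:]) / denom) if denom > 0 else 0.0

    def se(name):
        p = out.params[name]
        return float(p.stderr) if p.stderr is not None else math.nan

    return FCSFitResult(
        n_mol=float(out.params["n_mol"].value),
        tau_d=float(out.params["tau_d"].value),
        n_mol_se=se("n_mol"),
        tau_d_se=se("tau_d"),
        residual_lag1_autocorr=lag1,
        chi2_reduced=float(out.redchi),
    )


def calibrate_focus(
    standard_d: float, standard_tau: float, s_param: float,
    standard: DyeStandard | None = None,
) -> FocusCalibration:
    """Focus geometry from a free-dye standard.

    ``omega_r^2 = 4 D tau`` (3D diffusion through the waist) and the
    ellipsoidal-Gaussian confocal volume
    ``V = pi^(3/2) (omega_r^2)^(3/2) S``.
    """
    if standard_d <= 0 or standard_tau <= 0:
        raise ValueError("standard D and tau must be > 0")
    w2 = 4.0 * standard_d * standard_tau
    volume = math.pi ** 1.5 * w2 ** 1.5 * s_param
    return FocusCalibration(
        omega_r=math.sqrt(w2), s_param=s_param, volume=volume, standard=standard
    )


def focus_from_volume(volume: float, s_param: float) -> FocusCalibration:
    """Focus geometry back-computed from a reported confocal volume.

    Inverts ``V = pi^(3/2) (omega_r^2)^(3/2) S``; useful when only the
    rounded volume of a published calibration is available.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    w2 = (volume / (math.pi ** 1.5 * s_param)) ** (2.0 / 3.0)
    return FocusCalibration(omega_r=math.sqrt(w2), s_param=s_param, volume=volume)


def diffusion_from_residence(omega_r: float, tau_d: float) -> float:
    """Lateral diffusion coefficient ``D = omega_r^2 / (4 tau_D)``."""
    if omega_r <= 0 or tau_d <= 0:
        raise ValueError("omega_r and tau_d must be > 0")
    return omega_r**2 / (4.0 * tau_d)


@dataclass(frozen=True)
class DensityConversion:
    """Linear conversion constants between aqueous concentration, membrane
    surface density, and adsorption potential.

    ``alpha`` (V m^2) maps visible-target density to potential; the two
    adsorption coefficients (molecules um^-2 per nM aqueous) map aqueous dye
    concentrations to surface densities for the dipolar target and the PS.
    """

    alpha: float = 4.65e-19
    ads_coeff_dt: float = 30.0
    ads_coeff_ps: float = 57.0

    def __post_init__(self):
        for name in ("alpha", "ads_coeff_dt", "ads_coeff_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


DEFAULT_CONVERSION = DensityConversion()

_MODES = ("aq_nM_to_per_um2_dt", "aq_nM_to_per_um2_ps", "per_m2_to_V", "V_to_per_m2")


def density_conversions(
    value: float, mode: str, conv: DensityConversion = DEFAULT_CONVERSION
) -> float:
    """Convert between the units the calibration chain ties together.

    Modes: ``aq_nM_to_per_um2_dt`` and ``aq_nM_to_per_um2_ps`` (nM aqueous ->
    molecules um^-2 via the adsorption coefficients), ``per_m2_to_V`` and
    ``V_to_per_m2`` (surface density <-> adsorption potential via alpha).
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    if mode == "aq_nM_to_per_um2_dt":
        return value * conv.ads_coeff_dt
    if mode == "aq_nM_to_per_um2_ps":
        return value * conv.ads_coeff_ps
    if mode == "per_m2_to_V":
        return value * conv.alpha
    if mode == "V_to_per_m2":
        return value / conv.alpha
    raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
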