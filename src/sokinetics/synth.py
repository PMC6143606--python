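"""Synthetic planar-bilayer data with the statistical structure the
analysis pipeline assumes.

No raw experimental data accompany the model, so every pipeline input can be
generated here: rate-vs-adsorption-potential curves for both leaflet
configurations and several photosensitizer densities, boundary-potential
traces around illumination on/off events, and FCS autocorrelation decays.
Generators are pure functions of (parameters, seed) — two runs with the same
seed are bit-identical.

Default noise levels: 5% multiplicative lognormal on rates, 2% on
autocorrelation amplitudes, 0.3 mV additive Gaussian on potentials — the
scatter a well-behaved planar-bilayer / confocal setup produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model as m
from .fcs import FCSTrace, autocorrelation_model
from .fitting import PotentialTrace, RateDataset

__all__ = [
    "NoiseModel",
    "NO_NOISE",
    "DEFAULT_RATE_NOISE",
    "DEFAULT_TRACE_NOISE",
    "DEFAULT_FCS_NOISE",
    "default_design",
    "make_rate_datasets",
    "make_potential_trace",
    "make_fcs_trace",
]


@dataclass(frozen=True)
class NoiseModel:
    """Seeded observation noise applied to generated values.

    ``multiplicative_lognormal``: x -> x * exp(scale * z); ``scale`` is the
    log-sd, i.e. the CV for small scales.  ``additive_gaussian``: x -> x +
    scale * z in the native units.  ``none`` passes values through.
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("none", "multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.scale == 0.0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative_lognormal":
            return values * np.exp(self.scale * z)
        return values + self.scale * z

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NO_NOISE = NoiseModel()
DEFAULT_RATE_NOISE = NoiseModel("multiplicative_lognormal", 0.05)
DEFAULT_TRACE_NOISE = NoiseModel("additive_gaussian", 0.3e-3)   # 0.3 mV
DEFAULT_FCS_NOISE = NoiseModel("multiplicative_lognormal", 0.02)

#: default PS surface densities per photosensitizer, molecules m^-2.
#: The disulfonated dye follows its adsorption coefficient (57 um^-2/nM) at
#: 4 and 200 nM aqueous; the tetrasulfonated one uses round densities in the
#: sub/near-saturation range of the rate-vs-density curve.
_DEFAULT_PS_DENSITIES = {
    "AlPcS2": (228e12, 11400e12),
    "AlPcS4": (1000e12, 10000e12),
}


def default_design(labels=("AlPcS2", "AlPcS4")):
    """Measurement design: both sides x two PS densities per photosensitizer,
    adsorption potentials from 5 to 60 mV in 5 mV steps."""
    phi = np.arange(5.0, 60.0 + 1e-9, 5.0) * 1e-3
    design = []
    for label in labels:
        for density in _DEFAULT_PS_DENSITIES[label]:
            for side in ("cis", "trans"):
                design.append((label, side, density, phi))
    return design


def make_rate_datasets(
    rate_constants: dict,
    phys: m.PhysicalConstants = m.DEFAULT_PHYSICAL,
    alpha_s0: float = 30e-3,
    design=None,
    noise: NoiseModel = NO_NOISE,
) -> list[RateDataset]:
    """Generate rate-vs-potential curves from the kinetic model.

    Parameters
    ----------
    rate_constants : mapping of photosensitizer label -> RateConstants.
    alpha_s0 : invisible-target potential alpha*S_0 shared by all curves, V.
    design : list of (label, side, ps_density, phi_array); defaults to
        :func:`default_design` over the labels of ``rate_constants``.
    """
    if design is None:
        design = default_design(tuple(rate_constants))
    if not design:
        raise ValueError("empty measurement design")
    s0 = alpha_s0 / phys.alpha
    rng = noise.rng()
    out = []
    for label, side, density, phi in design:
        rc = rate_constants[label]
        phi = np.asarray(phi, dtype=float)
        inv_r = m.inverse_rate_curve(rc, side, density, phi, s0, phys.alpha)
        rate = noise.apply(1.0 / inv_r, rng)
        out.append(
            RateDataset(
                phi_ads=phi, rate=rate, side=side, ps_label=label,
                ps_density=density,
            )
        )
    return out


def make_potential_trace(
    rc: m.RateConstants,
    cfg: m.ExperimentConfig,
    phys: m.PhysicalConstants = m.DEFAULT_PHYSICAL,
    schedule=(("on", 60.0), ("off", 300.0)),
    sampling_dt: float = 0.5,
    noise: NoiseModel = NO_NOISE,
) -> PotentialTrace:
    """Generate a boundary-potential trace around an illumination schedule.

    Integrates the quasi-steady-state photobleaching dynamics, scales the
    relative potential by ``phi_ads = alpha * t0``, resamples on a uniform
    grid of ``sampling_dt``, and applies observation noise.
    """
    total = sum(d for _, d in schedule)
    if sampling_dt <= 0 or sampling_dt > total:
        raise ValueError("sampling_dt must be in (0, total schedule duration]")
    n_seg = max(int(np.ceil(total / sampling_dt)) * 4, 200)
    t, phi_rel, light = m.integrate_photobleaching(
        rc, cfg, list(schedule), n_per_segment=max(n_seg // len(schedule), 50)
    )
    t_grid = np.arange(0.0, total + sampling_dt * 0.5, sampling_dt)
    phi_ads = phys.alpha * cfg.t0
    phi_b = np.interp(t_grid, t, phi_rel) * phi_ads
    light_grid = np.interp(t_grid, t, light) > 0.5
    rng = noise.rng()
    phi_b = noise.apply(phi_b, rng)
    light_on_time = 0.0
    if not schedule[0][0] in ("on", True):
        # first light-on edge, if any
        on_idx = np.argmax(light_grid)
        light_on_time = float(t_grid[on_idx]) if light_grid.any() else 0.0
    return PotentialTrace(
        time=t_grid, phi_b=phi_b, phi_ads=phi_ads,
        light_on_time=light_on_time, light=light_grid.astype(float),
    )


def make_fcs_trace(
    n_mol: float,
    tau_d: float,
    lags: np.ndarray | None = None,
    noise: NoiseModel = NO_NOISE,
    label: str = "",
) -> FCSTrace:
    """Generate an FCS autocorrelation decay from the 2D diffusion model.

    Default lag grid: 64 log-spaced points between 1 us and 10 s.  Noise is
    applied to the correlation amplitude ``G - 1`` (multiplicative noise on G
    itself would be dominated by the baseline).
    """
    if lags is None:
        lags = np.logspace(-6, 1, 64)
    lags = np.asarray(lags, dtype=float)
    g = autocorrelation_model(lags, n_mol, tau_d)
    rng = noise.rng()
    if noise.kind == "multiplicative_lognormal":
        g = 1.0 + noise.apply(g - 1.0, rng)
    else:
        g = noise.apply(g, rng)
    return FCSTrace(lag=lags, g=g, label=label)
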