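"""CSV readers/writers, validated run configuration, and the pipeline runner.

All tabular I/O is RFC-4180 CSV with a mandatory header; units are encoded in
the column names (mV, per_um2, s) and converted to SI at this boundary.
Run configurations are YAML/JSON documents validated against a strict schema
(unknown keys are rejected with their location); the reference kinetic
constants ship as a packaged default configuration.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import model as m
from .fcs import FCSTrace
from .fitting import (
    FitSpec,
    PotentialTrace,
    RateDataset,
    bootstrap_uncertainty,
    global_fit,
)
from .synth import NoiseModel, make_rate_datasets

__all__ = [
    "RATE_COLUMNS",
    "load_rate_csv",
    "save_rate_csv",
    "load_trace_csv",
    "save_trace_csv",
    "load_fcs_csv",
    "save_fcs_csv",
    "RunConfig",
    "load_config",
    "default_config",
    "run_pipeline",
]

MV = 1e-3
PER_UM2 = 1e12

RATE_COLUMNS = ("phi_ads_mV", "rate_per_s", "side", "ps_label", "ps_density_per_um2")


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def load_rate_csv(path) -> list[RateDataset]:
    """Read rate curves, grouping rows by (side, ps_label, ps_density)."""
    df = pd.read_csv(path)
    _require_columns(df, RATE_COLUMNS, path)
    bad = df.index[df["rate_per_s"] <= 0]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: non-positive rate at line {bad[0] + 2}")
    bad = df.index[df["phi_ads_mV"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive phi_ads at line {bad[0] + 2}")
    out = []
    for (side, label, dens), grp in df.groupby(
        ["side", "ps_label", "ps_density_per_um2"], sort=True
    ):
        grp = grp.sort_values("phi_ads_mV")
        se = None
        if "rate_se_per_s" in grp.columns and grp["rate_se_per_s"].notna().all():
            se = grp["rate_se_per_s"].to_numpy()
        out.append(
            RateDataset(
                phi_ads=grp["phi_ads_mV"].to_numpy() * MV,
                rate=grp["rate_per_s"].to_numpy(),
                side=str(side),
                ps_label=str(label),
                ps_density=float(dens) * PER_UM2,
                rate_se=se,
            )
        )
    return out


def save_rate_csv(datasets, path) -> None:
    rows = []
    for ds in datasets:
        for i in range(len(ds)):
            row = {
                "phi_ads_mV": ds.phi_ads[i] / MV,
                "rate_per_s": ds.rate[i],
                "side": ds.side,
                "ps_label": ds.ps_label,
                "ps_density_per_um2": ds.ps_density / PER_UM2,
            }
            if ds.rate_se is not None:
                row["rate_se_per_s"] = ds.rate_se[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_trace_csv(path) -> PotentialTrace:
    """Read a potential trace (time_s, phi_b_mV, light 0/1).

    The normalisation plateau ``phi_ads`` is the mean potential before the
    first light-on sample (or the first sample if the trace starts lit).
    """
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "phi_b_mV", "light"), path)
    t = df["time_s"].to_numpy(float)
    phi = df["phi_b_mV"].to_numpy(float) * MV
    light = df["light"].to_numpy(float)
    on = np.flatnonzero(light > 0.5)
    if on.size and on[0] > 0:
        light_on_time = float(t[on[0]])
        phi_ads = float(np.mean(phi[: on[0]]))
    else:
        light_on_time = float(t[0])
        phi_ads = float(phi[0])
    return PotentialTrace(
        time=t, phi_b=phi, phi_ads=phi_ads,
        light_on_time=light_on_time, light=light,
    )


def save_trace_csv(trace: PotentialTrace, path) -> None:
    light = trace.light if trace.light is not None else (
        (trace.time >= trace.light_on_time).astype(float)
    )
    pd.DataFrame(
        {"time_s": trace.time, "phi_b_mV": trace.phi_b / MV, "light": light}
    ).to_csv(path, index=False)


def load_fcs_csv(path, label: str = "") -> FCSTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("lag_s", "g"), path)
    return FCSTrace(
        lag=df["lag_s"].to_numpy(float), g=df["g"].to_numpy(float),
        label=label or str(path),
    )


def save_fcs_csv(trace: FCSTrace, path) -> None:
    pd.DataFrame({"lag_s": trace.lag, "g": trace.g}).to_csv(path, index=False)


# --- run configuration ------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhysicalBlock(_Strict):
    alpha: float = 4.65e-19
    K_p: float = 4.4
    P_M: float = 0.80
    D_aq: float = 5.0e-9
    thickness: float = 4.0e-9
    tau_l_ref: float = 3.0e-6

    def to_constants(self) -> m.PhysicalConstants:
        return m.PhysicalConstants(**self.model_dump())


class RateBlock(_Strict):
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

    def to_constants(self) -> m.RateConstants:
        return m.RateConstants(**self.model_dump())


class FitBlock(_Strict):
    free_global: list[str] = ["k_w", "k_w0", "alpha_s0", "k_to"]
    free_local: list[str] = ["k_gen", "k_so"]
    fixed: dict[str, float] = Field(
        default_factory=lambda: {
            "k_ctm": 2.4e8, "k_mct": 5.5e7, "alpha": 4.65e-19, "k_pso": 0.0,
        }
    )
    n_starts: int = 16
    weight_mode: Literal["on_inverse_rate", "on_rate"] = "on_inverse_rate"
    n_boot: int = 0

    def to_spec(self) -> FitSpec:
        return FitSpec(
            free_global=tuple(self.free_global),
            free_local=tuple(self.free_local),
            fixed=dict(self.fixed),
            n_starts=self.n_starts,
            weight_mode=self.weight_mode,
        )


class SynthBlock(_Strict):
    enabled: bool = True
    alpha_s0_mV: float = 30.0
    noise_kind: Literal["none", "multiplicative_lognormal", "additive_gaussian"] = "none"
    noise_scale: float = 0.0


class ExperimentBlock(_Strict):
    side: Literal["cis", "trans"] = "cis"
    ps_label: str = "AlPcS2"
    ps_density_per_um2: float = 228.0
    t0_mV: float = 20.0
    s0_mV: float = 30.0

    def to_config(self, phys: m.PhysicalConstants) -> m.ExperimentConfig:
        return m.ExperimentConfig(
            side=self.side,
            ps_density=self.ps_density_per_um2 * PER_UM2,
            t0=self.t0_mV * MV / phys.alpha,
            s0=self.s0_mV * MV / phys.alpha,
        )


class RunConfig(_Strict):
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    physical_constants: PhysicalBlock = PhysicalBlock()
    rate_constants: dict[str, RateBlock]
    fit: FitBlock = FitBlock()
    synth: SynthBlock = SynthBlock()
    experiment: ExperimentBlock = ExperimentBlock()
    rate_files: list[str] = []
    seed: int = 0

    def constants_for(self, label: str) -> m.RateConstants:
        return self.rate_constants[label].to_constants()


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def default_config() -> RunConfig:
    """The packaged reference configuration (fitted kinetic constants)."""
    text = (
        importlib.resources.files("sokinetics.data")
        .joinpath("default_config.yaml")
        .read_text()
    )
    return RunConfig.model_validate(yaml.safe_load(text))


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Synthesise or load rate curves, fit globally, derive timescales.

    Returns (and optionally writes) a JSON-serialisable report echoing the
    configuration and seed alongside the estimates.
    """
    phys = config.physical_constants.to_constants()
    if config.synth.enabled:
        noise = NoiseModel(
            config.synth.noise_kind, config.synth.noise_scale, seed=config.seed
        )
        rcs = {lab: blk.to_constants() for lab, blk in config.rate_constants.items()}
        datasets = make_rate_datasets(
            rcs, phys, alpha_s0=config.synth.alpha_s0_mV * MV, noise=noise
        )
    else:
        if not config.rate_files:
            raise ValueError("synthesis disabled and no rate_files configured")
        datasets = []
        for f in config.rate_files:
            datasets.extend(load_rate_csv(f))

    spec = config.fit.to_spec()
    fit = global_fit(datasets, spec, seed=config.seed)
    if config.fit.n_boot >= 20:
        bootstrap_uncertainty(
            datasets, spec, n_boot=config.fit.n_boot, seed=config.seed, fit=fit
        )

    label = fit.labels[0]
    timescales = m.derived_timescales(
        fit.rate_constants(label), phys,
        ps_dt_distance=2e-9, target_density=0.1e18,
    )
    report = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "n_datasets": len(datasets),
        "n_points": fit.n_points,
        "estimates": fit.params,
        "stderr": fit.stderr,
        "bootstrap_halfwidths": fit.bootstrap_halfwidths,
        "fixed": fit.fixed,
        "bound_flags": fit.bound_flags,
        "k_to_lower_bound": fit.k_to_lower_bound,
        "alpha_s0_mV": fit.alpha_s0 / MV,
        "cost": fit.cost,
        "diagnostics": {
            k: v for k, v in fit.diagnostics.items() if k != "start_costs"
        },
        "timescales_ns": {
            "tau_dw_sum": timescales.tau_dw_sum * 1e9,
            "tau_t": timescales.tau_t * 1e9,
            "tau_to": timescales.tau_to * 1e9,
            "tau_dw_simple": timescales.tau_dw_simple * 1e9,
        },
        "delta_travel_nm": timescales.delta_travel * 1e9,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "fit_report.json").write_text(json.dumps(report, indent=2))
        rows = []
        for ds, res in zip(datasets, fit.residuals):
            for i in range(len(ds)):
                rows.append(
                    {
                        "ps_label": ds.ps_label,
                        "side": ds.side,
                        "ps_density_per_um2": ds.ps_density / PER_UM2,
                        "phi_ads_mV": ds.phi_ads[i] / MV,
                        "rate_per_s": ds.rate[i],
                        "weighted_residual": float(res[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "residuals.csv", index=False)
    return report
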