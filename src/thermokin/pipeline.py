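"""End-to-end orchestration: thermograms → kinetics → thermodynamics → ANN.

A validated :class:`PipelineConfig` fully determines a run; the config, an
input manifest (SHA-256 of every file read or written) and a structured stage
log are serialized into the output directory, so a run is reconstructible
from its output bundle alone. Identical config + seed ⇒ byte-identical
numeric tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as tio
from .ann import AnnMetrics, AnnModel, AnnSpec, build_dataset, train_ann
from .exceptions import PipelineStageError
from .isoconversional import EaProfile, fit_isoconversional, get_method
from .kissinger import (KissingerResult, frequency_factors, kissinger_regression,
                        thermo_params)
from .models import ReactionModel
from .simulate import (HeatingProgram, KineticTriplet, NoiseSpec, add_noise,
                       conversion_to_thermogram, simulate_conversion)
from .thermogram import (ConversionCurve, PeakInfo, Thermogram, compute_conversion,
                         find_peak, rates_at_conversions, temperatures_at_conversions)
from .yields import ComponentWeighing, YieldSet, compute_yields

__all__ = ["PipelineConfig", "SyntheticScenario", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class SyntheticScenario(BaseModel):
    """Ground-truth kinetics and heating programs for a simulated study."""

    Ea_kJ_mol: float = 105.0
    A_per_min: float = 1e9
    model: str = "F1"
    T_start_K: float = 450.0
    T_end_K: float = 850.0
    step_K: float = 0.25
    betas: Sequence[float] = (10.0, 20.0, 30.0, 40.0)
    w0_mg: float = 10.0
    wf_mg: float = 1.5
    mass_noise_sd: float = 0.0
    drift_per_K: float = 0.0


class InputFile(BaseModel):
    path: str
    beta: Optional[float] = None
    units: Literal["K", "C"] = "K"


class AnnConfig(BaseModel):
    enabled: bool = True
    hidden_layers: Sequence[int] = (4,)
    activation: Literal["tanh", "logistic"] = "tanh"
    n_points: int = 840
    max_epochs: int = 400
    l2_grid: Sequence[float] = (1e-4, 1e-3, 1e-2)


class WeighingConfig(BaseModel):
    component: str
    before_g: float
    after_g: float


class YieldConfig(BaseModel):
    feed_g: float
    weighings: Sequence[WeighingConfig]


class PipelineConfig(BaseModel):
    """Everything a run needs; validated before any computation starts."""

    scenario: Optional[SyntheticScenario] = Field(default_factory=SyntheticScenario)
    input_files: Optional[Sequence[InputFile]] = None
    alpha_start: float = 0.10
    alpha_stop: float = 0.80
    alpha_step: float = 0.05
    methods: Sequence[str] = ("KAS", "FWO", "STARINK", "FRIEDMAN")
    smooth_window: int = 11
    window_K: Optional[tuple[float, float]] = None
    tm_policy: Union[Literal["lowest_beta_peak", "highest_beta_peak"], float] = (
        "lowest_beta_peak"
    )
    a_time_unit: Literal["s", "min"] = "s"
    ann: AnnConfig = Field(default_factory=AnnConfig)
    yields_input: Optional[YieldConfig] = None
    outdir: Optional[str] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.scenario is None and not self.input_files:
            raise ValueError("either a synthetic scenario or input files required")
        if not (0 < self.alpha_start < self.alpha_stop < 1):
            raise ValueError("need 0 < alpha_start < alpha_stop < 1")
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        for m in self.methods:
            get_method(m)
        return self

    def alpha_grid(self) -> np.ndarray:
        n = int(round((self.alpha_stop - self.alpha_start) / self.alpha_step)) + 1
        return self.alpha_start + self.alpha_step * np.arange(n)


@dataclass
class PipelineResult:
    """Bundle of every stage's output plus provenance records."""

    config: PipelineConfig
    thermograms: list[Thermogram]
    curves: list[ConversionCurve]
    peaks: list[PeakInfo]
    profiles: dict[str, EaProfile]
    kissinger: KissingerResult
    thermo: pd.DataFrame
    yields_: Optional[YieldSet] = None
    ann_model: Optional[AnnModel] = None
    ann_metrics: Optional[AnnMetrics] = None
    log: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    written: list = field(default_factory=list)


def _stage(result: PipelineResult, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                result.log.append({"stage": name, "status": "FAILED",
                                   "error": str(exc)})
                raise PipelineStageError(name, exc) from exc
            result.log.append({"stage": name, "status": "ok"})
            return False

    return _Ctx()


def _load_thermograms(config: PipelineConfig, result: PipelineResult,
                      outdir: Optional[Path]) -> list[Thermogram]:
    if config.input_files:
        tgs = []
        for spec in config.input_files:
            tg = tio.read_thermogram_csv(spec.path, units=spec.units, beta=spec.beta)
            result.manifest[str(spec.path)] = tio.sha256_of(spec.path)
            tgs.append(tg)
        return tgs
    sc = config.scenario
    triplet = KineticTriplet(Ea=sc.Ea_kJ_mol * 1e3, A=sc.A_per_min,
                             model=ReactionModel(sc.model))
    tgs = []
    for k, beta in enumerate(sc.betas):
        program = HeatingProgram(beta=beta, T_start=sc.T_start_K,
                                 T_end=sc.T_end_K, step=sc.step_K)
        curve = simulate_conversion(triplet, program)
        tg = conversion_to_thermogram(curve, w0=sc.w0_mg, wf=sc.wf_mg)
        if sc.mass_noise_sd > 0 or sc.drift_per_K != 0:
            tg = add_noise(tg, NoiseSpec(mass_noise_sd=sc.mass_noise_sd,
                                         drift=sc.drift_per_K,
                                         seed=config.seed + k))
        if outdir is not None:
            path = outdir / f"thermogram_beta{beta:g}.csv"
            tio.write_thermogram_csv(tg, path)
            result.manifest[str(path)] = tio.sha256_of(path)
            result.written.append(path)
        tgs.append(tg)
    return tgs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage; any failure names its stage.

    When ``config.outdir`` is set, all tables, the config echo, the stage log
    and the manifest are written there; on failure a ``FAILED`` marker file
    records the failing stage, and tables written so far are retained.
    """
    outdir = None
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config, thermograms=[], curves=[], peaks=[],
                            profiles={}, kissinger=None, thermo=pd.DataFrame())
    try:
        _run_stages(config, result, outdir)
    except PipelineStageError as err:
        if outdir is not None:
            (outdir / "FAILED").write_text(f"stage: {err.stage}\nerror: {err.original}\n")
            _write_provenance(config, result, outdir)
        raise
    if outdir is not None:
        _write_provenance(config, result, outdir)
    return result


def _run_stages(config: PipelineConfig, result: PipelineResult, outdir):
    with _stage(result, "load"):
        result.thermograms = _load_thermograms(config, result, outdir)

    with _stage(result, "conversion"):
        result.curves = [
            compute_conversion(tg, window=config.window_K,
                               smooth_window=config.smooth_window)
            for tg in result.thermograms
        ]

    with _stage(result, "peaks"):
        result.peaks = [find_peak(c) for c in result.curves]

    with _stage(result, "isoconversional"):
        grid = config.alpha_grid()
        table = temperatures_at_conversions(result.curves, grid)
        rates = rates_at_conversions(result.curves, grid)
        for m in config.methods:
            method = get_method(m)
            result.profiles[method.name] = fit_isoconversional(
                method, table, rates if method.needs_rate else None
            )
        if outdir is not None:
            p = tio.write_iso_table_csv(table, outdir / "iso_temperatures.csv")
            result.written.append(p)

    with _stage(result, "kissinger_thermo"):
        result.kissinger = kissinger_regression(result.peaks)
        by_beta = {p.beta: p for p in result.peaks}
        tp_low = by_beta[min(by_beta)].Tp
        tp_high = by_beta[max(by_beta)].Tp
        if config.tm_policy == "lowest_beta_peak":
            Tm = tp_low
        elif config.tm_policy == "highest_beta_peak":
            Tm = tp_high
        else:
            Tm = float(config.tm_policy)
        rows = []
        A_map = {}
        for name, prof in result.profiles.items():
            for i, fit in enumerate(prof.fits):
                ff = frequency_factors(fit.Ea, result.peaks)
                T_alpha = float(np.nanmean(table.T[i]))
                tp = thermo_params(fit.Ea, ff.A, T_alpha=T_alpha, Tp=tp_low,
                                   Tm=Tm, alpha=fit.alpha,
                                   a_time_unit=config.a_time_unit)
                A_map[(name, fit.alpha)] = ff.A
                rows.append({
                    "method": name, "alpha": fit.alpha,
                    "Ea_kJ_mol": fit.Ea / 1e3, "A_per_min": ff.A,
                    "dH_kJ_mol": tp.dH / 1e3, "dG_kJ_mol": tp.dG / 1e3,
                    "dS_J_molK": tp.dS, "r2": fit.r2,
                })
        result.thermo = pd.DataFrame(rows)
        if outdir is not None:
            result.written.append(
                tio.write_ea_profiles_csv(result.profiles,
                                          outdir / "ea_profiles.csv", A_map))
            result.written.append(
                tio.write_thermo_csv(result.thermo, outdir / "thermo.csv"))

    if config.yields_input is not None:
        with _stage(result, "yields"):
            ws = [ComponentWeighing(w.component, w.before_g, w.after_g)
                  for w in config.yields_input.weighings]
            result.yields_ = compute_yields(ws, config.yields_input.feed_g)
            if outdir is not None:
                result.written.append(
                    tio.write_yields_csv(result.yields_, outdir / "yields.csv"))

    if config.ann.enabled:
        with _stage(result, "ann"):
            data = build_dataset(result.curves, config.ann.n_points)
            spec = AnnSpec(hidden_layers=tuple(config.ann.hidden_layers),
                           activation=config.ann.activation,
                           max_epochs=config.ann.max_epochs,
                           seed=config.seed,
                           l2_grid=tuple(config.ann.l2_grid))
            result.ann_model, result.ann_metrics = train_ann(data, spec)
            if outdir is not None:
                path = outdir / "ann_model.json"
                path.write_text(result.ann_model.to_json())
                result.written.append(path)
                mpath = outdir / "ann_metrics.json"
                mpath.write_text(json.dumps(result.ann_metrics.__dict__,
                                            indent=2, sort_keys=True))
                result.written.append(mpath)


def _write_provenance(config: PipelineConfig, result: PipelineResult, outdir: Path):
    tio.save_config(json.loads(config.model_dump_json()), outdir / "config.yaml")
    for p in result.written:
        result.manifest.setdefault(str(p), tio.sha256_of(p))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
    (outdir / "run_log.json").write_text(
        json.dumps(result.log, indent=2, sort_keys=True))
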