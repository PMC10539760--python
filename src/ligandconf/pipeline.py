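"""End-to-end pipeline orchestration: simulate -> fit -> report.

A :class:`RunConfig` (validated pydantic model, loadable from YAML)
selects stages and their parameters; :func:`run_pipeline` executes them in
dependency order, writes every artifact as JSON/CSV into the output
directory, and returns a manifest with per-file SHA-256 checksums.  All
inter-stage data flows through serialized files; identical config + seed
gives identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import exsy as exsy_mod
from . import popfit as popfit_mod
from . import rex as rex_mod
from . import shiftlist as shiftlist_mod
from . import synthetic as syn

log = logging.getLogger("ligandconf")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class ExsyStage(BaseModel):
    Ea_kcal_mol: float = 19.9
    k_ref_per_s: float = 1.3863
    t_ref_K: float = 300.0
    temperatures_K: list[float] = [300.0, 305.0, 310.0]
    mixing_times_s: list[float] = list(syn.STANDARD_MIXING_TIMES)
    noise_sigma: float = 0.0
    model_tag: str = "no-t1"


class RexStage(BaseModel):
    preset: str = "hindered_biaryl"
    t_min_K: float = 300.0
    t_max_K: float = 3300.0
    replicas: int = Field(12, ge=1)
    sweeps: int = Field(50_000, ge=1)
    start_angle_deg: float = 90.0
    step_deg: float = 60.0
    exchange_interval: int = 1
    bins: int = 72
    burn_in: float = 0.1


class PopfitStage(BaseModel):
    true_weights: list[float] = [0.7, 0.3]
    n_conformers: Optional[int] = None
    noise_sigma: float = 0.0
    prune_below: float = 0.01
    ensemble_json: Optional[str] = None  # fit a user ensemble instead of simulating


class ShiftsStage(BaseModel):
    compound: int = Field(2, ge=1, le=3)
    text_file: Optional[str] = None


class RunConfig(BaseModel):
    """Validated pipeline configuration."""

    stages: list[str] = ["exsy", "rex", "popfit", "shifts"]
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    exsy: ExsyStage = ExsyStage()
    rex: RexStage = RexStage()
    popfit: PopfitStage = PopfitStage()
    shifts: ShiftsStage = ShiftsStage()

    def validate_inputs(self) -> None:
        known = {"exsy", "rex", "popfit", "shifts"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "popfit" in self.stages and self.popfit.ensemble_json:
            if not Path(self.popfit.ensemble_json).exists():
                raise ValueError(
                    f"popfit stage: ensemble file not found: {self.popfit.ensemble_json}"
                )
        if "shifts" in self.stages and self.shifts.text_file:
            if not Path(self.shifts.text_file).exists():
                raise ValueError(f"shifts stage: text file not found: {self.shifts.text_file}")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded, so identical experiments hash identically)."""
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        raise ValueError(f"invalid pipeline config: {err}") from err
    cfg.validate_inputs()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {
        "_provenance": {
            "tool": "ligandconf",
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        },
        **payload,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _stage_exsy(cfg: RunConfig, out: Path) -> list:
    p = cfg.exsy
    truth = syn.ArrheniusTruth.from_rate(
        Ea=p.Ea_kcal_mol, k_ref=p.k_ref_per_s, t_ref=p.t_ref_K,
        temperatures=tuple(p.temperatures_K),
    )
    ds = syn.gen_exsy_dataset(
        truth, mixing_times=p.mixing_times_s,
        noise=syn.NoiseSpec(sigma=p.noise_sigma, seed=cfg.seed),
    )
    csv_path = out / "exsy_curves.csv"
    ds.to_dataframe().to_csv(csv_path, index=False)
    fits = exsy_mod.fit_dataset(ds, model_tag=p.model_tag)
    arr = exsy_mod.fit_arrhenius(fits)
    fit_path = out / "exsy_fit.json"
    _write_json(
        fit_path,
        {
            "rate_fits": [f.as_dict() for f in fits],
            "arrhenius": arr.as_dict(),
            "eyring_dG_at_base_K": exsy_mod.eyring_barrier(fits[0].k, fits[0].temperature),
            "ground_truth": ds.provenance,
        },
        cfg,
    )
    return [csv_path, fit_path]


def _stage_rex(cfg: RunConfig, out: Path) -> list:
    p = cfg.rex
    pot = syn.gen_torsion_potential(p.preset)
    ladder = rex_mod.build_ladder(p.t_min_K, p.t_max_K, p.replicas)
    traj = rex_mod.run_rex(
        pot, ladder, sweeps=p.sweeps, start_angle=p.start_angle_deg,
        step_deg=p.step_deg, exchange_interval=p.exchange_interval, seed=cfg.seed,
    )
    report = rex_mod.make_report(traj, pot, bins=p.bins, burn_in=p.burn_in)
    traj_path = out / "rex_base_trajectory.csv"
    series = traj.base_angles()
    np.savetxt(
        traj_path,
        np.column_stack([np.arange(1, series.size + 1), series]),
        delimiter=",", header="sweep,angle_deg", comments="", fmt=["%d", "%.6f"],
    )
    report_path = out / "rex_report.json"
    _write_json(report_path, report.as_dict(), cfg)
    return [traj_path, report_path]


def _stage_popfit(cfg: RunConfig, out: Path) -> list:
    p = cfg.popfit
    if p.ensemble_json:
        raise NotImplementedError(
            "fitting user-supplied ensembles goes through popfit.fit_populations directly"
        )
    ensemble, observed = syn.gen_conformer_ensemble(
        true_weights=p.true_weights,
        n_conformers=p.n_conformers,
        noise=syn.NoiseSpec(sigma=p.noise_sigma, seed=cfg.seed),
    )
    fit = popfit_mod.fit_populations(ensemble, observed, prune_below=p.prune_below)
    report = popfit_mod.goodness_report(fit, observed)
    fit_path = out / "population_fit.json"
    _write_json(
        fit_path,
        {
            "weights": fit.weights,
            "ssd": fit.ssd,
            "pruned": list(fit.pruned),
            "goodness": report,
            "ground_truth": observed.provenance,
        },
        cfg,
    )
    return [fit_path]


def _stage_shifts(cfg: RunConfig, out: Path) -> list:
    p = cfg.shifts
    if p.text_file:
        text = Path(p.text_file).read_text()
        sl = shiftlist_mod.parse_shift_list(text, compound=Path(p.text_file).stem)
    else:
        sl = shiftlist_mod.load_compound(p.compound)
    payload = sl.as_dict()
    try:
        ra = shiftlist_mod.rotamer_fractions(sl)
        payload["rotamer_fractions"] = {k: float(v) for k, v in ra.fractions.items()}
        payload["rotamer_messages"] = list(ra.messages)
    except ValueError as err:
        payload["rotamer_fractions"] = None
        payload["rotamer_messages"] = [str(err)]
    payload["total_protons"] = str(shiftlist_mod.total_protons(sl))
    path = out / "shiftlist.json"
    _write_json(path, payload, cfg)
    return [path]


_STAGE_ORDER = ["shifts", "exsy", "rex", "popfit"]
_STAGE_FN = {
    "exsy": _stage_exsy,
    "rex": _stage_rex,
    "popfit": _stage_popfit,
    "shifts": _stage_shifts,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest lists each completed stage with its artifacts and
    SHA-256 checksums.  On stage failure the manifest still records the
    completed stages and re-raises.
    """
    cfg.validate_inputs()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "tool": "ligandconf",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    try:
        for stage in _STAGE_ORDER:
            if stage not in cfg.stages:
                continue
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            files = _STAGE_FN[stage](cfg, out)
            manifest["stages"][stage] = {
                "artifacts": {f.name: _sha256(f) for f in files},
            }
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
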