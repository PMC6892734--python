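"""Config-driven orchestration: run every analysis and write a report bundle.

Outputs (all deterministic given the seed): ``table1.csv`` (the
nonadherence sensitivity table), ``ue.csv`` (per-participant unaccounted
energy), ``sweep.csv`` (both elimination-sweep directions, stacked),
``tertiles.json``, ``baseline.json``, a ``run.log`` echoing the
configuration, and ``manifest.json`` with a SHA-256 hash of every data
product.  The input cohort is never mutated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accounting import cohort_unaccounted_energy, elimination_sweep
from .diagnostics import baseline_comparison
from .effects import FULL_COVARIATES, tertile_effect_report
from .sensitivity import format_sensitivity_table, sensitivity_table
from .simulate import SimConfig, read_cohort, simulate_cohort, write_cohort

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("dlwsens")

MINIMAL_COVARIATES = ("cohort", "tee_post")


@dataclass
class RunConfig:
    """What to run and where to put it."""

    outdir: Path
    cohort_path: Path | None = None
    sim_config: SimConfig | None = None
    seed: int = 0
    sensitivity: bool = True
    accounting: bool = True
    effects: bool = True
    diagnostics: bool = True
    per_protocol_only: bool = True
    sweep_step: float = 25.0
    ue_band: float = 250.0
    plots: bool = False
    covariates: tuple = MINIMAL_COVARIATES
    tertile_covariates: tuple = FULL_COVARIATES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (self.sensitivity or self.accounting or self.effects or self.diagnostics):
            raise ValueError("at least one analysis must be enabled")
        if self.cohort_path is None and self.sim_config is None:
            self.sim_config = SimConfig()


def _effect_to_dict(est) -> dict | None:
    if est is None:
        return None
    d = dataclasses.asdict(est)
    d["n_per_arm"] = dict(est.n_per_arm)
    return d


def run_all(cfg: RunConfig) -> dict:
    """Run the enabled analyses; returns {output name: path}."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        logger.info("dlwsens %s starting; seed=%d", __version__, cfg.seed)
        if cfg.cohort_path is not None:
            logger.info("loading cohort from %s", cfg.cohort_path)
            cohort = read_cohort(cfg.cohort_path)
        else:
            logger.info("simulating cohort: %s", cfg.sim_config)
            cohort = simulate_cohort(cfg.sim_config, seed=cfg.seed)
            path = cfg.outdir / "cohort.csv"
            write_cohort(cohort, path)
            outputs["cohort"] = path
        analysis = cohort[cohort["per_protocol"]] if cfg.per_protocol_only else cohort
        analysis = analysis.reset_index(drop=True)
        logger.info("analysis set: %d of %d participants", len(analysis), len(cohort))

        if cfg.sensitivity:
            _stage(outputs, "table1", cfg, lambda: _write_sensitivity(analysis, cfg))
        if cfg.accounting:
            _stage(outputs, "ue", cfg, lambda: _write_ue(cohort, cfg))
            _stage(outputs, "sweep", cfg, lambda: _write_sweep(cohort, cfg))
        if cfg.effects:
            _stage(outputs, "tertiles", cfg, lambda: _write_tertiles(analysis, cfg))
        if cfg.diagnostics:
            _stage(outputs, "baseline", cfg, lambda: _write_baseline(analysis, cfg))

        manifest = {
            name: {"path": path.name, "sha256": _sha256(path)}
            for name, path in outputs.items()
        }
        manifest_path = cfg.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        outputs["manifest"] = manifest_path
        logger.info("done; %d outputs", len(outputs))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs


def _stage(outputs: dict, name: str, cfg: RunConfig, fn) -> None:
    try:
        outputs[name] = fn()
    except Exception:
        logger.exception("stage %r failed", name)
        raise RuntimeError(f"analysis stage {name!r} failed") from None


def _write_sensitivity(analysis: pd.DataFrame, cfg: RunConfig) -> Path:
    table = sensitivity_table(analysis, covariates=cfg.covariates)
    path = cfg.outdir / "table1.csv"
    table.to_csv(path, index=False, float_format="%.6f")
    display = format_sensitivity_table(table)
    display.to_csv(cfg.outdir / "table1_display.csv", index=False)
    logger.info("sensitivity table written: effect at p=0 is %.1f kcal/day", table["effect_kcal"][0])
    return path


def _write_ue(cohort: pd.DataFrame, cfg: RunConfig) -> Path:
    ue = cohort_unaccounted_energy(cohort)
    out = pd.DataFrame({"id": cohort["id"], "unaccounted_energy": ue})
    path = cfg.outdir / "ue.csv"
    out.to_csv(path, index=False, float_format="%.6f")
    n_in = int((ue.abs() <= cfg.ue_band).sum())
    logger.info("%d of %d observations within +/-%g kcal/day", n_in, len(ue), cfg.ue_band)
    return path


def _write_sweep(cohort: pd.DataFrame, cfg: RunConfig) -> Path:
    frames = []
    for direction in ("low-intake-relative-to-TEE", "low-TEE-relative-to-intake"):
        curve = elimination_sweep(cohort, direction, step=cfg.sweep_step, covariates=cfg.covariates)
        frame = curve.to_frame()
        frame.insert(0, "direction", direction)
        frames.append(frame)
    path = cfg.outdir / "sweep.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    if cfg.plots:
        from .plots import plot_sweep

        plot_sweep(frames, cfg.outdir / "sweep.png")
    return path


def _write_tertiles(analysis: pd.DataFrame, cfg: RunConfig) -> Path:
    report = tertile_effect_report(analysis, covariates=cfg.tertile_covariates)
    payload = {
        "unadjusted": {str(t): _effect_to_dict(e) for t, e in report.unadjusted.items()},
        "adjusted": {str(t): _effect_to_dict(e) for t, e in report.adjusted.items()},
        "odds_ratio": report.odds_ratio,
        "or_ci": [report.or_ci_low, report.or_ci_high],
        "or_p": report.or_p,
        "tertile_sizes": [int((report.assignments == t).sum()) for t in (1, 2, 3)],
    }
    path = cfg.outdir / "tertiles.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _write_baseline(analysis: pd.DataFrame, cfg: RunConfig) -> Path:
    comp = baseline_comparison(analysis)
    path = cfg.outdir / "baseline.json"
    path.write_text(json.dumps(dataclasses.asdict(comp), indent=2, sort_keys=True) + "\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
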