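"""Seeded synthetic-cohort generator emulating the feeding trial's structure.

The generator produces a parallel three-arm weight-loss-maintenance cohort
with the statistical features the analysis pipeline exercises:

* a true low-vs-high-carbohydrate TEE effect (default 280 kcal/day),
  applied symmetrically about the moderate arm and attenuated per
  participant by any real nonadherence fraction;
* pre- and post-weight-loss baseline TEE correlated with the follow-up
  latent TEE at configurable couplings (post > pre by default), so the
  post-weight-loss baseline is the stronger predictor;
* DLW measurement noise placed on the rCO2 scale — the published TEE
  values are rCO2 times the Weir factor at the *assigned* arm's food
  quotient, so real nonadherence biases measured TEE exactly as the
  sensitivity analysis assumes;
* energy conservation: true intake equals true TEE plus the
  body-composition energy flux, so unaccounted energy is pure reporting
  and measurement error unless the intake-reporting model says otherwise;
* a flat-slope intake-reporting model (reported intake regresses toward
  the cohort mean and is shifted downward), the canonical behaviour of
  dietary self-report, which makes unaccounted energy negatively
  correlated with true expenditure.

All randomness flows from one seed through named substreams, so toggling
one noise source does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .accounting import stored_energy_rate
from .dlw import ARM_COMPOSITIONS, DEFAULT_QUOTIENTS, MacronutrientQuotients, weir_factor
from .sensitivity import fq_under_nonadherence

ARM_LABELS = tuple(ARM_COMPOSITIONS)

__all__ = ["SimConfig", "SchemaError", "COHORT_COLUMNS", "simulate_cohort", "write_cohort", "read_cohort"]

#: Exact cohort CSV schema (header order).
COHORT_COLUMNS = [
    "id",
    "arm",
    "cohort",
    "sex",
    "age",
    "pct_weight_loss",
    "post_wl_weight",
    "tee_pre",
    "tee_post",
    "tee_wk10",
    "tee_wk20",
    "rco2",
    "intake_reported",
    "delta_fm",
    "delta_ffm",
    "per_protocol",
    "p_nonadherence",
]


class SchemaError(ValueError):
    """Raised when a cohort file does not match the expected schema."""


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cohort parameters.

    Energy values are kcal/day, masses kg, durations days.  The defaults
    encode the trial conditions the pipeline is calibrated against: 120
    participants in three arms (20/60, 40/40, 60/20 percent energy
    carbohydrate/fat, protein the residual 20%), a 280 kcal/day true
    low-vs-high effect, and a post-weight-loss baseline that couples to
    follow-up TEE (0.85) more strongly than the pre-weight-loss baseline
    (0.65).  Between-person and measurement noise magnitudes are not
    published for the trial; the defaults (between-person SD 350, DLW
    noise 120 per measurement, reporting-error SD 300 with mean
    underreporting 300 and tracking slope 0.5) are realistic literature
    magnitudes — see docs/methods.md.
    """

    n: int = 120
    true_effect_low_vs_high: float = 280.0
    mean_tee_high_arm: float = 2700.0
    coupling_pre: float = 0.65
    coupling_post: float = 0.85
    pre_post_corr: float = 0.70
    between_person_sd: float = 350.0
    tee_noise_sd: float = 120.0
    intake_tracking: float = 0.5
    intake_report_bias_mean: float = -300.0
    intake_report_bias_sd: float = 300.0
    nonadherence_mean: float = 0.0
    nonadherence_sd: float = 0.0
    cohort_levels: int = 2
    sex_effect: float = 250.0
    cohort_effect: float = 60.0
    p_female: float = 0.7
    mean_pre_offset: float = 250.0
    delta_fm_sd: float = 0.4
    delta_ffm_sd: float = 0.4
    followup_days: float = 140.0
    weight_stability_bound: float = 50.0
    quotients: MacronutrientQuotients = field(default=DEFAULT_QUOTIENTS)

    def __post_init__(self) -> None:
        if self.n < 6:
            raise ValueError(f"need n >= 6, got {self.n}")
        for name in ("coupling_pre", "coupling_post", "pre_post_corr"):
            v = getattr(self, name)
            if not (-1.0 < v < 1.0):
                raise ValueError(f"{name} = {v!r} outside (-1, 1)")
        for name in (
            "between_person_sd",
            "tee_noise_sd",
            "intake_report_bias_sd",
            "nonadherence_sd",
            "delta_fm_sd",
            "delta_ffm_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.nonadherence_mean <= 1.0):
            raise ValueError("nonadherence_mean must lie in [0, 1]")
        if self.cohort_levels < 1:
            raise ValueError("cohort_levels must be >= 1")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")
        # fail early on an infeasible correlation structure
        self._cholesky()

    def _correlation(self) -> np.ndarray:
        # order: (pre, post, follow-up latent)
        return np.array(
            [
                [1.0, self.pre_post_corr, self.coupling_pre],
                [self.pre_post_corr, 1.0, self.coupling_post],
                [self.coupling_pre, self.coupling_post, 1.0],
            ]
        )

    def _cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self._correlation())
        except np.linalg.LinAlgError:
            raise ValueError(
                "baseline/follow-up correlation matrix is not positive definite: "
                f"pre_post_corr={self.pre_post_corr}, coupling_pre={self.coupling_pre}, "
                f"coupling_post={self.coupling_post}"
            ) from None

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


_ARM_DIRECTION = {"low": 1.0, "moderate": 0.0, "high": -1.0}


def simulate_cohort(
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    return_latent: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; deterministic given ``seed``.

    With ``return_latent=True`` also returns the unobserved quantities
    (true TEE, true intake, actual RQ, stored-energy rate) used by
    calibration tests.
    """
    ss = np.random.SeedSequence(seed)
    r_struct, r_latent, r_meas, r_bc, r_intake, r_nonadh = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    n = cfg.n

    # -- structure: arms (randomized), enrollment cohort, demographics
    arms = np.array(ARM_LABELS * (n // 3 + 1))[:n]
    r_struct.shuffle(arms)
    cohort_level = (np.arange(n) % cfg.cohort_levels) + 1
    sex = np.where(r_struct.random(n) < cfg.p_female, "F", "M")
    age = np.round(r_struct.uniform(20, 60, n), 1)
    pct_wl = np.round(r_struct.uniform(8, 14, n), 1)

    # -- latent TEE structure (kcal/day)
    base_mean = (
        cfg.mean_tee_high_arm
        + cfg.true_effect_low_vs_high / 2.0
        + np.where(sex == "M", cfg.sex_effect, 0.0)
        + cfg.cohort_effect * (cohort_level - 1)
    )
    if cfg.between_person_sd > 0:
        chol = cfg._cholesky()
        latent = r_latent.standard_normal((n, 3)) @ chol.T * cfg.between_person_sd
    else:
        latent = np.zeros((n, 3))
    tee_pre_true = base_mean + cfg.mean_pre_offset + latent[:, 0]
    tee_post_true = base_mean + latent[:, 1]
    fup_latent = base_mean + latent[:, 2]

    # -- nonadherence and the true diet effect it attenuates
    p_nonadh = np.clip(
        r_nonadh.normal(cfg.nonadherence_mean, cfg.nonadherence_sd, n)
        if cfg.nonadherence_sd > 0
        else np.full(n, cfg.nonadherence_mean),
        0.0,
        1.0,
    )
    direction = np.vectorize(_ARM_DIRECTION.get)(arms).astype(float)
    fup_true = fup_latent + direction * (cfg.true_effect_low_vs_high / 2.0) * (1.0 - p_nonadh)

    # -- DLW: actual RQ follows the effective diet; noise lives on rCO2;
    #    published TEE assumes full adherence (the arm FQ at p = 0)
    rq_actual = np.array(
        [fq_under_nonadherence(a, p, cfg.quotients) for a, p in zip(arms, p_nonadh)]
    )
    fq_assumed = np.array([fq_under_nonadherence(a, 0.0, cfg.quotients) for a in arms])
    w_actual = weir_factor(rq_actual)
    w_assumed = weir_factor(fq_assumed)
    rco2_true = fup_true / w_actual
    rco2_noise_sd = cfg.tee_noise_sd / w_actual
    rco2_wk10 = rco2_true + r_meas.normal(0.0, 1.0, n) * rco2_noise_sd
    rco2_wk20 = rco2_true + r_meas.normal(0.0, 1.0, n) * rco2_noise_sd
    tee_wk10 = rco2_wk10 * w_assumed
    tee_wk20 = rco2_wk20 * w_assumed
    rco2 = (rco2_wk10 + rco2_wk20) / 2.0
    tee_pre = tee_pre_true + r_meas.normal(0.0, cfg.tee_noise_sd, n)
    tee_post = tee_post_true + r_meas.normal(0.0, cfg.tee_noise_sd, n)

    # -- body composition and energy conservation
    delta_fm = r_bc.normal(0.0, cfg.delta_fm_sd, n)
    delta_ffm = r_bc.normal(0.0, cfg.delta_ffm_sd, n)
    stored = stored_energy_rate(delta_fm, delta_ffm, cfg.followup_days)
    intake_true = fup_true + stored
    per_protocol = np.abs(stored) <= cfg.weight_stability_bound

    # -- reported intake: off-protocol energy unreported, then flat-slope
    #    reporting error toward the cohort mean plus mean underreporting
    reported_base = (1.0 - p_nonadh) * intake_true
    mu_intake = float(np.mean(intake_true))
    intake_reported = (
        mu_intake
        + cfg.intake_tracking * (reported_base - mu_intake)
        + cfg.intake_report_bias_mean
        + r_intake.normal(0.0, cfg.intake_report_bias_sd, n)
    )
    intake_reported = np.maximum(intake_reported, 1.0)

    post_wl_weight = np.round(
        82.0 + 0.018 * (tee_post_true - np.mean(base_mean)) + r_struct.normal(0.0, 9.0, n), 1
    )

    cohort = pd.DataFrame(
        {
            "id": [f"P{i + 1:04d}" for i in range(n)],
            "arm": arms,
            "cohort": cohort_level,
            "sex": sex,
            "age": age,
            "pct_weight_loss": pct_wl,
            "post_wl_weight": post_wl_weight,
            "tee_pre": tee_pre,
            "tee_post": tee_post,
            "tee_wk10": tee_wk10,
            "tee_wk20": tee_wk20,
            "rco2": rco2,
            "intake_reported": intake_reported,
            "delta_fm": delta_fm,
            "delta_ffm": delta_ffm,
            "per_protocol": per_protocol,
            "p_nonadherence": p_nonadh,
        }
    )
    if not return_latent:
        return cohort
    latent_df = pd.DataFrame(
        {
            "id": cohort["id"],
            "tee_pre_true": tee_pre_true,
            "tee_post_true": tee_post_true,
            "tee_fup_true": fup_true,
            "rq_actual": rq_actual,
            "rco2_true": rco2_true,
            "stored_rate": stored,
            "intake_true": intake_true,
        }
    )
    return cohort, latent_df


_DTYPES: Mapping[str, type] = {
    "id": str,
    "arm": str,
    "cohort": int,
    "sex": str,
    "age": float,
    "pct_weight_loss": float,
    "post_wl_weight": float,
    "tee_pre": float,
    "tee_post": float,
    "tee_wk10": float,
    "tee_wk20": float,
    "rco2": float,
    "intake_reported": float,
    "delta_fm": float,
    "delta_ffm": float,
    "per_protocol": bool,
    "p_nonadherence": float,
}


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (energies kept to 1e-6 precision)."""
    _validate_columns(cohort.columns)
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS, float_format="%.6f")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema; a 0-row file is valid."""
    df = pd.read_csv(path)
    _validate_columns(df.columns)
    df = df[COHORT_COLUMNS]
    return df.astype(_DTYPES)


def _validate_columns(columns) -> None:
    have = list(columns)
    missing = [c for c in COHORT_COLUMNS if c not in have]
    extra = [c for c in have if c not in COHORT_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise SchemaError("; ".join(parts))
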