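"""Food-quotient, respiratory-quotient and Weir-factor arithmetic.

The doubly-labeled-water (DLW) method measures the rate of CO2 production
(rCO2, L/day) and converts it to total energy expenditure (TEE, kcal/day)
through the Weir equation.  Because the Weir factor depends on the
respiratory quotient (RQ), and because RQ equals the food quotient (FQ) of
the diet during weight and body-composition stability, the assumed diet
composition enters every DLW TEE value.  This module holds that arithmetic:
computing FQ from a macronutrient composition, the Weir factor, TEE from gas
exchange, and rescaling an existing TEE value under an alternative FQ
assumption (the primitive behind the nonadherence sensitivity analysis).

Units: energy in kcal/day, gas volumes in L/day, compositions as fractions
of total energy in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DietComposition",
    "MacronutrientQuotients",
    "GasExchange",
    "DEFAULT_QUOTIENTS",
    "WEIR_O2",
    "WEIR_CO2",
    "RQ_MIN",
    "RQ_MAX",
    "ARM_COMPOSITIONS",
    "ARM_LABELS",
    "food_quotient",
    "weir_factor",
    "tee_from_gas",
    "rescale_tee",
]

#: Weir equation coefficients, kcal per liter of O2 and CO2 respectively.
#: rO2 is eliminated through rO2 = rCO2 / RQ, giving kcal/L-CO2 =
#: WEIR_CO2 + WEIR_O2 / RQ.
WEIR_O2 = 3.941
WEIR_CO2 = 1.106

#: Physiological range accepted for RQ / FQ values.
RQ_MIN = 0.65
RQ_MAX = 1.05


@dataclass(frozen=True)
class DietComposition:
    """Macronutrient composition of a diet as fractions of total energy.

    Parameters
    ----------
    carb, fat, protein :
        Fractions of energy from carbohydrate, fat and protein.  Each must
        lie in [0, 1] and they must sum to 1 within 1e-9.
    """

    carb: float
    fat: float
    protein: float

    def __post_init__(self) -> None:
        for name in ("carb", "fat", "protein"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} fraction {v!r} outside [0, 1]")
        total = self.carb + self.fat + self.protein
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"energy fractions sum to {total!r}, not 1")

    @classmethod
    def from_carb_fat(cls, carb: float, fat: float) -> "DietComposition":
        """Build a composition with protein as the residual 1 - carb - fat."""
        return cls(carb, fat, 1.0 - carb - fat)

    def mix(self, other: "DietComposition", lam: float) -> "DietComposition":
        """Component-wise mixture (1 - lam) * self + lam * other."""
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"mixing fraction {lam!r} outside [0, 1]")
        return DietComposition(
            (1.0 - lam) * self.carb + lam * other.carb,
            (1.0 - lam) * self.fat + lam * other.fat,
            (1.0 - lam) * self.protein + lam * other.protein,
        )


@dataclass(frozen=True)
class MacronutrientQuotients:
    """RQ of pure oxidation of each macronutrient (dimensionless).

    The defaults (1.000 carbohydrate, 0.710 fat, 0.810 protein) are the
    standard literature values; they also reproduce the trial arms'
    published FQ values (0.7880 for 20/60/20 carb/fat/protein, 0.9040 for
    60/20/20) to four decimals.
    """

    carb: float = 1.000
    fat: float = 0.710
    protein: float = 0.810

    def __post_init__(self) -> None:
        if not (0.6 < self.fat < self.protein < self.carb <= 1.0):
            raise ValueError(
                "macronutrient quotients must satisfy "
                f"0.6 < fat < protein < carb <= 1.0, got {self}"
            )


DEFAULT_QUOTIENTS = MacronutrientQuotients()

#: The three parallel feeding arms: percent energy from carbohydrate/fat of
#: 20/60 (low), 40/40 (moderate) and 60/20 (high), protein always the
#: residual 20%.
ARM_COMPOSITIONS = {
    "low": DietComposition.from_carb_fat(0.20, 0.60),
    "moderate": DietComposition.from_carb_fat(0.40, 0.40),
    "high": DietComposition.from_carb_fat(0.60, 0.20),
}
ARM_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class GasExchange:
    """A CO2 production rate (L/day) with the RQ used to interpret it."""

    rco2: float
    rq: float

    def __post_init__(self) -> None:
        if not self.rco2 > 0:
            raise ValueError(f"rco2 must be positive, got {self.rco2!r}")
        if not (RQ_MIN <= self.rq <= RQ_MAX):
            raise ValueError(f"rq {self.rq!r} outside [{RQ_MIN}, {RQ_MAX}]")


def food_quotient(
    comp: DietComposition,
    quotients: MacronutrientQuotients = DEFAULT_QUOTIENTS,
) -> float:
    """Energy-weighted food quotient of a diet composition.

    FQ = carb * q_carb + fat * q_fat + protein * q_protein; linear in the
    composition, hence the FQ of a mixture of diets is the mixture of FQs.
    """
    return (
        comp.carb * quotients.carb
        + comp.fat * quotients.fat
        + comp.protein * quotients.protein
    )


def weir_factor(rq, o2: float = WEIR_O2, co2: float = WEIR_CO2):
    """kcal of energy expended per liter of CO2 at respiratory quotient ``rq``.

    Abridged Weir equation with rO2 eliminated via rO2 = rCO2/RQ:
    W(RQ) = co2 + o2 / RQ = 1.106 + 3.941/RQ by default.  Strictly
    decreasing in RQ.  Accepts scalars or arrays.
    """
    rq = np.asarray(rq, dtype=float)
    if np.any(rq <= 0):
        raise ValueError("rq must be positive")
    if np.any(rq < RQ_MIN) or np.any(rq > RQ_MAX):
        raise ValueError(f"rq outside physiological range [{RQ_MIN}, {RQ_MAX}]")
    out = co2 + o2 / rq
    return float(out) if out.ndim == 0 else out


def tee_from_gas(gas: GasExchange) -> float:
    """TEE (kcal/day) implied by a CO2 production rate at a given RQ."""
    return gas.rco2 * weir_factor(gas.rq)


def rescale_tee(tee_old, fq_old, fq_new):
    """Re-express a DLW TEE value under an alternative FQ assumption.

    DLW measures rCO2; the published TEE is rCO2 * W(fq_old).  If the
    subject's true RQ was ``fq_new`` instead, the corrected TEE is
    rCO2 * W(fq_new) = tee_old * W(fq_new) / W(fq_old).  Multiplicative,
    order-independent across chained FQ changes, and exactly inverse under
    swapping the two FQ arguments.  Accepts scalars or arrays.
    """
    return tee_old * weir_factor(fq_new) / weir_factor(fq_old)
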