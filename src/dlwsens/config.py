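"""Package configuration: physiological constants and analysis settings.

A config file (YAML or JSON) can override the macronutrient quotients
(``quotients.{carb,fat,prot}``), the Weir coefficients (``weir.{o2,co2}``)
and the body-composition energy densities (``energy_density.{fm,ffm}``);
unset keys keep their defaults.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .accounting import RHO_FFM, RHO_FM
from .dlw import WEIR_CO2, WEIR_O2, MacronutrientQuotients

__all__ = ["default_config", "load_config", "quotients_from_config"]


def default_config() -> dict:
    return {
        "quotients": {"carb": 1.000, "fat": 0.710, "prot": 0.810},
        "weir": {"o2": WEIR_O2, "co2": WEIR_CO2},
        "energy_density": {"fm": RHO_FM, "ffm": RHO_FFM},
    }


def load_config(path: str | Path | None = None) -> dict:
    """Defaults deep-merged with overrides from a YAML/JSON file."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data:
        _merge(cfg, data)
    return cfg


def _merge(base: dict, override: dict) -> None:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)


def quotients_from_config(cfg: dict) -> MacronutrientQuotients:
    q = cfg["quotients"]
    return MacronutrientQuotients(carb=q["carb"], fat=q["fat"], protein=q["prot"])
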