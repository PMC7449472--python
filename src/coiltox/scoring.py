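"""Device scores: the model-1 geometric predictor and alternative candidates.

The core predictor scores an atomizer as

    score = L / (SA * n)

with L the total coil wire length (mm), SA the total wick outer surface
area (mm²) and n the wraps per coil.  A long coil concentrates more heat,
a large wick spreads it over more e-liquid, and more wraps distribute the
contact points — so a high score flags a build expected to run hot and
degrade more solvent into carbonyls.  Alternative candidate scores
(notably ones including the power setting W, in watts) are expressed as
monomials over the four variables {L, SA, n, W} and evaluated through the
same registry, so candidates can be ranked on equal footing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import sympy

from coiltox.device_model import Aggregation, AtomizerDevice, effective_geometry

__all__ = [
    "ScoreModel",
    "MissingVariableError",
    "model1_score",
    "evaluate_score_model",
    "builtin_models",
    "load_models",
    "save_models",
]

_VARIABLES = ("L", "SA", "n", "W")
_SYMBOLS = {name: sympy.Symbol(name, positive=True) for name in _VARIABLES}


class MissingVariableError(ValueError):
    """A score expression references a variable the device does not supply."""


def _parse_monomial(expression: str) -> tuple[float, dict[str, float]]:
    """Parse an expression into (coefficient, exponents over L/SA/n/W).

    Only products, quotients and real powers of the four variables (with a
    positive numeric coefficient) are accepted; sums or other functions are
    rejected so every score stays positive, finite and unit-checkable.
    """
    try:
        expr = sympy.sympify(expression, locals=dict(_SYMBOLS), evaluate=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ValueError(f"cannot parse score expression {expression!r}: {exc}") from exc
    extra = expr.free_symbols - set(_SYMBOLS.values())
    if extra:
        raise ValueError(
            f"expression {expression!r} uses undeclared variables "
            f"{sorted(str(s) for s in extra)}; allowed: {list(_VARIABLES)}"
        )
    coefficient, factors = expr.as_coeff_Mul()
    powers = {} if factors == 1 else factors.as_powers_dict()
    exponents: dict[str, float] = {}
    for base, power in powers.items():
        if base not in _SYMBOLS.values() or not power.is_number:
            raise ValueError(
                f"expression {expression!r} is not a monomial in {list(_VARIABLES)}"
            )
        exponents[str(base)] = float(power)
    if not coefficient.is_number or not coefficient.is_positive:
        raise ValueError(
            f"expression {expression!r} must have a positive numeric coefficient"
        )
    return float(coefficient), exponents


@dataclass(frozen=True)
class ScoreModel:
    """A named monomial formula over {L, SA, n, W} producing a device score."""

    name: str
    expression: str
    description: str = ""
    _coefficient: float = field(init=False, repr=False, compare=False)
    _exponents: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("model name must be non-empty")
        coefficient, exponents = _parse_monomial(self.expression)
        object.__setattr__(self, "_coefficient", coefficient)
        object.__setattr__(self, "_exponents", exponents)

    @property
    def requires_power(self) -> bool:
        return self._exponents.get("W", 0.0) != 0.0

    def __call__(
        self, L: float, SA: float, n: float, W: Optional[float] = None
    ) -> float:
        for label, value in (("L", L), ("SA", SA), ("n", n)):
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValueError(f"score variable {label} must be positive, got {value!r}")
        values = {"L": L, "SA": SA, "n": n}
        if self.requires_power:
            if W is None:
                raise MissingVariableError(
                    f"model '{self.name}' requires power W but none was supplied"
                )
            if not math.isfinite(W) or W <= 0:
                raise ValueError(f"score variable W must be positive, got {W!r}")
            values["W"] = W
        result = self._coefficient
        for var, exponent in self._exponents.items():
            result *= values.get(var, 1.0) ** exponent
        return float(result)


def model1_score(L: float, SA: float, n: float) -> float:
    """The geometric predictor L / (SA * n), in mm⁻¹."""
    for label, value in (("L", L), ("SA", SA), ("n", n)):
        if value is None or not math.isfinite(value) or value <= 0:
            raise ValueError(f"{label} must be positive, got {value!r}")
    return L / (SA * n)


def evaluate_score_model(
    model: ScoreModel,
    device: AtomizerDevice,
    aggregation: Aggregation = Aggregation.SUM_WIRES,
) -> float:
    """Evaluate a score model on a device's effective geometry and power."""
    length, area, wraps = effective_geometry(device, aggregation)
    return model(L=length, SA=area, n=wraps, W=device.power)


def builtin_models() -> list[ScoreModel]:
    """The built-in candidate scores: the geometric model and two power variants."""
    return [
        ScoreModel(
            "model1",
            "L / (SA * n)",
            "coil length over (wick surface area × wraps); the geometric predictor",
        ),
        ScoreModel(
            "power_model_1a",
            "W * L / (SA * n)",
            "power-weighted geometric score",
        ),
        ScoreModel(
            "power_model_2a",
            "W / (L * SA)",
            "power over (coil length × wick surface area)",
        ),
    ]


def _check_unique(models: Iterable[ScoreModel]) -> list[ScoreModel]:
    out: list[ScoreModel] = []
    seen: set[str] = set()
    for model in models:
        if model.name in seen:
            raise ValueError(f"duplicate score model name: {model.name!r}")
        seen.add(model.name)
        out.append(model)
    return out


def load_models(path, include_builtins: bool = True) -> list[ScoreModel]:
    """Load user score models from a JSON mapping name -> expression (or
    name -> {expression, description}); optionally prepend the builtins."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"models file {path} must be a JSON object")
    user = []
    for name, value in raw.items():
        if isinstance(value, str):
            user.append(ScoreModel(name, value))
        elif isinstance(value, dict):
            user.append(ScoreModel(name, value["expression"], value.get("description", "")))
        else:
            raise ValueError(f"models file {path}: entry {name!r} must be a string or object")
    models = (builtin_models() + user) if include_builtins else user
    return _check_unique(models)


def save_models(models: Iterable[ScoreModel], path) -> None:
    payload = {
        m.name: {"expression": m.expression, "description": m.description}
        for m in _check_unique(models)
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
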