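"""System configuration parsing and validation.

A transducer system is described by a JSON object::

    {
      "capacity": 1.0,
      "gibbs_catabolic": 1.0,
      "leak": 0.0,
      "pathways": [
        {"stoichiometry": 1.0, "weight": 0.8},
        {"stoichiometry": 2.0, "weight": 0.2}
      ]
    }

Validation collects *all* violations (each with a stable machine-readable
code) rather than stopping at the first, so a user can fix a config in one
round trip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .core import Pathway, TransducerSystem

__all__ = [
    "Violation",
    "ConfigError",
    "validate_system_config",
    "system_from_config",
    "load_system",
    "system_to_config",
]


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


class ConfigError(ValueError):
    """Raised when a system config is invalid; carries all violations."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid system config:\n" + "\n".join(str(v) for v in violations)
        )


def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def validate_system_config(raw: Any) -> list[Violation]:
    """Return every violation found in a parsed config document."""
    out: list[Violation] = []
    if not isinstance(raw, dict):
        return [Violation("not-an-object", f"config must be a JSON object, got {type(raw).__name__}")]

    cap = raw.get("capacity", 1.0)
    if not _is_number(cap):
        out.append(Violation("bad-type", f"capacity must be a number, got {cap!r}"))
    elif cap <= 0:
        out.append(Violation("nonpositive-capacity", f"capacity must be > 0, got {cap}"))

    gc = raw.get("gibbs_catabolic", 1.0)
    if not _is_number(gc):
        out.append(Violation("bad-type", f"gibbs_catabolic must be a number, got {gc!r}"))
    elif gc <= 0:
        out.append(
            Violation("nonpositive-gibbs", f"gibbs_catabolic must be > 0, got {gc}")
        )

    leak = raw.get("leak", 0.0)
    if not _is_number(leak):
        out.append(Violation("bad-type", f"leak must be a number, got {leak!r}"))
    elif leak < 0:
        out.append(Violation("negative-leak", f"leak must be >= 0, got {leak}"))

    pathways = raw.get("pathways")
    if not isinstance(pathways, list) or len(pathways) < 1:
        out.append(
            Violation("missing-pathways", "config must list at least one pathway")
        )
        return out

    weights = []
    for k, p in enumerate(pathways):
        if not isinstance(p, dict):
            out.append(Violation("bad-type", f"pathway {k} must be an object"))
            continue
        n = p.get("stoichiometry")
        w = p.get("weight")
        if not _is_number(n):
            out.append(
                Violation("bad-type", f"pathway {k}: stoichiometry must be a number")
            )
        elif n < 0:
            out.append(
                Violation(
                    "negative-stoichiometry",
                    f"pathway {k}: stoichiometry must be >= 0, got {n}",
                )
            )
        if not _is_number(w):
            out.append(Violation("bad-type", f"pathway {k}: weight must be a number"))
        else:
            if not 0.0 <= w <= 1.0:
                out.append(
                    Violation(
                        "weight-out-of-range",
                        f"pathway {k}: weight must be in [0, 1], got {w}",
                    )
                )
            weights.append(w)

    if len(weights) == len(pathways):
        wsum = math.fsum(weights)
        if abs(wsum - 1.0) > 1e-12:
            out.append(
                Violation("weights-sum", f"pathway weights sum to {wsum:g}, expected 1")
            )
    return out


def system_from_config(raw: Any) -> TransducerSystem:
    """Build a validated TransducerSystem from a parsed config document."""
    violations = validate_system_config(raw)
    if violations:
        raise ConfigError(violations)
    return TransducerSystem(
        pathways=tuple(
            Pathway(p["stoichiometry"], p["weight"]) for p in raw["pathways"]
        ),
        capacity=raw.get("capacity", 1.0),
        gibbs_catabolic=raw.get("gibbs_catabolic", 1.0),
        leak=raw.get("leak", 0.0),
    )


def load_system(path: str | Path) -> TransducerSystem:
    """Load a system from a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    return system_from_config(raw)


def system_to_config(system: TransducerSystem) -> dict:
    """Round-trippable config dict for a system (used in metadata sidecars)."""
    return {
        "capacity": system.capacity,
        "gibbs_catabolic": system.gibbs_catabolic,
        "leak": system.leak,
        "pathways": [
            {"stoichiometry": p.stoichiometry, "weight": p.weight}
            for p in system.pathways
        ],
    }
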