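"""SW-score → predicted mutation-rate calibration.

Longer, more perfect repeats both score higher against a perfect array and
mutate faster, so a marker's repeat-alignment score carries information about
its expected per-meiosis mutation rate.  The published per-marker predictions
are reproduced, to within printing precision, by a two-parameter power law
``rate = a * SWS**b`` fitted by least squares in log-log space — a
reverse-engineered calibration (the original mapping is unpublished), stored
and refittable here.  Rates are per 100 meioses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["PowerLawModel", "fit_power_law", "predict_rate"]


@dataclass
class PowerLawModel:
    """``predict(s) = a * s**b`` with the calibration pairs retained."""

    a: float
    b: float
    pairs: list[tuple[float, float]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    rms_log_residual: float = 0.0

    def predict(self, sws: float) -> float:
        if sws <= 0:
            raise ValueError("SW score must be positive")
        return self.a * sws ** self.b

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "a": self.a, "b": self.b, "pairs": self.pairs,
            "labels": self.labels, "rms_log_residual": self.rms_log_residual,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerLawModel":
        d = json.loads(Path(path).read_text())
        return cls(d["a"], d["b"], [tuple(p) for p in d["pairs"]],
                   d["labels"], d["rms_log_residual"])


def fit_power_law(
    pairs: Sequence[tuple[float, float]],
    labels: Optional[Sequence[str]] = None,
) -> PowerLawModel:
    """Least-squares line fit in (ln SWS, ln rate) space.

    Requires at least 3 pairs, all strictly positive (a rate of zero has no
    logarithm and no place in a power law).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 calibration pairs")
    s = np.array([p[0] for p in pairs], float)
    r = np.array([p[1] for p in pairs], float)
    if np.any(s <= 0) or np.any(r <= 0):
        raise ValueError("all scores and rates must be positive")
    b, log_a = np.polyfit(np.log(s), np.log(r), 1)
    a = float(np.exp(log_a))
    resid = np.log(r) - (log_a + b * np.log(s))
    return PowerLawModel(
        a=a, b=float(b),
        pairs=[(float(x), float(y)) for x, y in pairs],
        labels=list(labels) if labels is not None else [],
        rms_log_residual=float(np.sqrt(np.mean(resid ** 2))),
    )


def predict_rate(model: PowerLawModel, sws: "float | Sequence[float]"):
    """Predicted rate(s) per 100 meioses; a list input also returns the mean."""
    if np.isscalar(sws):
        return model.predict(float(sws))
    rates = [model.predict(float(s)) for s in sws]
    return rates, float(np.mean(rates))
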