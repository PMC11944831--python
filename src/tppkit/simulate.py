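"""Synthetic TPP dataset generator with exact ground truth.

Emulates TMT-style relative-abundance melt tables over a 10-point 37-67 °C
gradient, two conditions (vehicle vs treatment) and two biological
replicates.  A configurable fraction of proteins carries a true thermal
shift: the treatment curve's ``a`` parameter is re-derived so that the
closed-form Tm moves by exactly the injected ΔTm while ``b`` and ``plateau``
are held fixed, keeping the ground truth exact rather than approximate.

Noise is multiplicative Gaussian on the relative abundance, truncated at
zero, drawn i.i.d. per measured point; replicates are independent noise
redraws around the same true curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .melting import MELT_TABLE_COLUMNS, sigmoid_model

__all__ = ["SimulationConfig", "ConfigurationError", "simulate_dataset", "write_melt_table"]


class ConfigurationError(ValueError):
    """A simulation parameter violates its constraint; message names the field."""


def _default_temperatures() -> tuple[float, ...]:
    return tuple(np.linspace(37.0, 67.0, 10).round(6))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated TPP experiment.

    Baseline curves are drawn by sampling a true melting temperature
    (uniform on ``tm_range``), slope offset ``b`` and plateau, then deriving
    ``a`` from the closed-form Tm relation, so every baseline Tm lands inside
    the configured range (default 46-62 °C, inside the 45-70 °C span of the
    human proteome).
    """

    n_proteins: int = 100
    temperatures: tuple[float, ...] = field(default_factory=_default_temperatures)
    conditions: tuple[str, str] = ("vehicle", "treatment")
    n_replicates: int = 2
    shift_fraction: float = 0.1
    delta_tm_mean: float = 3.0
    delta_tm_sd: float = 1.0
    noise_sd: float = 0.05
    tm_range: tuple[float, float] = (46.0, 62.0)
    b_range: tuple[float, float] = (8.0, 12.0)
    plateau_range: tuple[float, float] = (0.0, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be a positive integer")
        t = np.asarray(self.temperatures, float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ConfigurationError("temperatures must be strictly increasing")
        if np.any(t <= 0):
            raise ConfigurationError("temperatures must be positive (°C)")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ConfigurationError("conditions must be a pair of distinct labels")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be a positive integer")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ConfigurationError("shift_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.delta_tm_sd < 0:
            raise ConfigurationError("delta_tm_sd must be >= 0")
        for name in ("tm_range", "b_range", "plateau_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} must satisfy low <= high")
        if not (0.0 <= self.plateau_range[0] and self.plateau_range[1] < 0.5):
            raise ConfigurationError("plateau_range must lie in [0, 0.5) so Tm stays defined")
        if self.b_range[0] <= 0:
            raise ConfigurationError("b_range must be positive")
        if self.tm_range[0] <= 0:
            raise ConfigurationError("tm_range must be positive (°C)")


def _a_for_tm(tm: float, b: float, plateau: float) -> float:
    """Invert the closed-form Tm relation for the slope numerator ``a``."""
    return tm * (b - math.log(0.5 / (0.5 - plateau)))


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format melt table plus its ground-truth table.

    Returns ``(melt, truth)``: ``melt`` has one row per protein x condition x
    replicate x temperature with columns ``protein_id, condition, replicate,
    temperature_c, rel_abundance``; ``truth`` has one row per protein with the
    generating parameters per condition, true Tm values, the injected ΔTm and
    the shifter flag.  Identical config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.temperatures, float)
    n = config.n_proteins
    vehicle, treatment = config.conditions

    tm_v = rng.uniform(*config.tm_range, size=n)
    b = rng.uniform(*config.b_range, size=n)
    plateau = rng.uniform(*config.plateau_range, size=n)
    n_shift = int(round(config.shift_fraction * n))
    is_shifter = np.zeros(n, dtype=bool)
    if n_shift:
        is_shifter[rng.choice(n, size=n_shift, replace=False)] = True
    delta = np.where(is_shifter, rng.normal(config.delta_tm_mean, config.delta_tm_sd, size=n), 0.0)
    tm_t = tm_v + delta

    width = len(str(n - 1)) if n > 1 else 1
    ids = np.array([f"P{i:0{width}d}" for i in range(n)])

    records = []
    for i in range(n):
        a_v = _a_for_tm(tm_v[i], b[i], plateau[i])
        a_t = _a_for_tm(tm_t[i], b[i], plateau[i]) if is_shifter[i] else a_v
        for cond, a in ((vehicle, a_v), (treatment, a_t)):
            truth_curve = sigmoid_model(t, a, b[i], plateau[i])
            for rep in range(1, config.n_replicates + 1):
                if config.noise_sd > 0:
                    y = truth_curve * (1.0 + rng.normal(0.0, config.noise_sd, size=t.size))
                    y = np.maximum(y, 0.0)
                else:
                    y = truth_curve
                records.append(
                    pd.DataFrame(
                        {
                            "protein_id": ids[i],
                            "condition": cond,
                            "replicate": rep,
                            "temperature_c": t,
                            "rel_abundance": y,
                        }
                    )
                )
    melt = pd.concat(records, ignore_index=True)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "is_shifter": is_shifter,
            "b": b,
            "plateau": plateau,
            "a_vehicle": [_a_for_tm(tm_v[i], b[i], plateau[i]) for i in range(n)],
            "a_treatment": [
                _a_for_tm(tm_t[i], b[i], plateau[i]) if is_shifter[i]
                else _a_for_tm(tm_v[i], b[i], plateau[i])
                for i in range(n)
            ],
            "tm_vehicle": tm_v,
            "tm_treatment": tm_t,
            "delta_tm": delta,
        }
    )
    return melt, truth


def write_melt_table(melt: pd.DataFrame, path) -> None:
    """Write a long-format melt table as TSV; round-trips through
    :func:`tppkit.melting.read_melt_table`."""
    if melt is None or len(melt) == 0:
        raise ValueError("refusing to write an empty melt table")
    missing = [c for c in MELT_TABLE_COLUMNS if c not in melt.columns]
    if missing:
        raise ValueError(f"melt table missing columns: {missing}")
    melt[MELT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
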