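"""Per-profile sigmoid melting-curve fitting and Tm extraction.

A melting profile is the relative soluble (non-denatured) fraction of one
protein measured over a temperature gradient, normalized to the lowest
(reference) temperature.  The melting model is the standard three-parameter
sigmoid used throughout thermal proteome profiling:

    f(T) = (1 - plateau) / (1 + exp(b - a / T)) + plateau

with ``a > 0`` (°C-scaled slope numerator), ``b > 0`` (dimensionless offset)
and ``plateau`` in [0, 1) (non-denaturable fraction).  Temperatures are in
degrees Celsius, the convention for TPP gradients; because the model divides
``a`` by T, fits are unit-sensitive and Kelvin input will not work.

The melting temperature Tm is the half-denaturation point, the temperature at
which f(T) = 0.5.  It has the closed form

    Tm = a / (b - ln(0.5 / (0.5 - plateau)))

and is only defined when plateau < 0.5 (otherwise the curve never reaches
half denaturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeltProfile",
    "MeltFit",
    "MIN_POINTS",
    "TM_EXTRAPOLATION_C",
    "sigmoid_model",
    "normalize_to_reference",
    "fit_melting_curve",
    "compute_tm",
    "curve_quality_filter",
    "delta_tm",
    "replicate_tm_correlation",
    "read_melt_table",
    "fit_all_profiles",
    "write_fit_table",
]

#: Minimum number of distinct temperatures required to attempt a 3-parameter fit.
MIN_POINTS = 5

#: Tm values are reported only inside [min(grid) - 5, max(grid) + 5] °C;
#: crossings further out are wild extrapolations and treated as undefined.
TM_EXTRAPOLATION_C = 5.0

MELT_TABLE_COLUMNS = ["protein_id", "condition", "replicate", "temperature_c", "rel_abundance"]


class NormalizationError(ValueError):
    """Reference temperature missing or reference abundance non-positive."""


class InputError(ValueError):
    """Profile does not satisfy the preconditions of an operation."""


class StatisticsError(ValueError):
    """Too few data points for the requested statistic."""


@dataclass(frozen=True)
class MeltProfile:
    """One protein x condition x replicate melting profile.

    ``temperatures_c`` must be strictly increasing; abundances are relative
    (non-negative, ~1 at the reference temperature).
    """

    protein_id: str
    condition: str
    replicate: int
    temperatures_c: np.ndarray
    rel_abundance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        y = np.asarray(self.rel_abundance, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise InputError("temperatures and abundances must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InputError("temperatures must be strictly increasing and unique")
        if np.any(y < 0):
            raise InputError("relative abundances must be non-negative")
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "rel_abundance", y)


@dataclass
class MeltFit:
    """Fitted sigmoid parameters and quality metrics for one profile."""

    a: float = math.nan
    b: float = math.nan
    plateau: float = math.nan
    rss: float = math.nan
    r_squared: float = math.nan
    tm_c: float | None = None
    valid: bool = False
    protein_id: str = ""
    condition: str = ""
    replicate: int = 0


def sigmoid_model(temperature_c, a: float, b: float, plateau: float = 0.0):
    """Evaluate the three-parameter melting sigmoid at ``temperature_c`` (°C).

    Strictly decreasing in T for a, b > 0; tends to ``plateau`` at high T and
    to values near 1 at low T.  Raises for non-positive temperatures (the
    model divides by T).
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t <= 0):
        raise InputError("temperature must be positive (°C)")
    # exp argument is clipped to keep overflow out of the optimizer's path
    z = np.clip(b - a / t, -700.0, 700.0)
    out = (1.0 - plateau) / (1.0 + np.exp(z)) + plateau
    if np.isscalar(temperature_c):
        return float(out)
    return out


def normalize_to_reference(profile: MeltProfile, reference_temp_c: float | None = None) -> MeltProfile:
    """Divide all abundances by the abundance at the reference temperature.

    The reference defaults to the lowest temperature of the profile (37 °C in
    the standard gradient).  Idempotent: a profile already at 1.0 at the
    reference is returned unchanged in value.
    """
    t = profile.temperatures_c
    if reference_temp_c is None:
        reference_temp_c = float(t[0])
    idx = np.flatnonzero(np.isclose(t, reference_temp_c))
    if idx.size == 0:
        raise NormalizationError(
            f"reference temperature {reference_temp_c} °C not present in profile "
            f"{profile.protein_id}/{profile.condition}/r{profile.replicate}"
        )
    ref = float(profile.rel_abundance[idx[0]])
    if ref <= 0:
        raise NormalizationError(
            f"reference abundance must be positive, got {ref} for {profile.protein_id}"
        )
    return MeltProfile(
        protein_id=profile.protein_id,
        condition=profile.condition,
        replicate=profile.replicate,
        temperatures_c=t,
        rel_abundance=profile.rel_abundance / ref,
    )


def compute_tm(
    a: float,
    b: float,
    plateau: float,
    window: tuple[float, float] | None = None,
) -> float | None:
    """Closed-form melting temperature, or ``None`` when undefined.

    Tm = a / (b - ln(0.5 / (0.5 - plateau))).  Undefined when plateau >= 0.5
    (the curve never drops to half) or when the crossing falls outside the
    extrapolation ``window`` (°C bounds), when one is given.
    """
    if not np.isfinite(a) or not np.isfinite(b) or not np.isfinite(plateau):
        return None
    if plateau >= 0.5:
        return None
    denom = b - math.log(0.5 / (0.5 - plateau))
    if denom <= 0:
        return None
    tm = a / denom
    if window is not None and not (window[0] <= tm <= window[1]):
        return None
    return tm


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Coarse data-driven starts: plateau from the tail, Tm from the half-crossing."""
    pl0 = float(np.clip(np.min(y), 0.0, 0.85))
    half = (1.0 + pl0) / 2.0
    below = np.flatnonzero(y <= half)
    if below.size and below[0] > 0:
        i = below[0]
        # linear interpolation of the half-crossing between bracketing points
        y0, y1 = y[i - 1], y[i]
        frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.5
        tm0 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    elif below.size:
        tm0 = float(t[0])
    else:
        tm0 = float(t[-1])
    tm0 = max(tm0, 1.0)
    starts = []
    for b0 in (10.0, 6.0, 16.0):
        shift = math.log(0.5 / (0.5 - pl0)) if pl0 < 0.5 else 0.0
        a0 = max(tm0 * (b0 - shift), 1.0)
        starts.append((a0, b0, min(pl0, 0.45)))
    return starts


def fit_melting_curve(
    profile: MeltProfile,
    max_nfev: int = 2000,
) -> MeltFit:
    """Bounded least-squares fit of the melting sigmoid to one profile.

    Tries a coarse set of data-driven starts and keeps the best (lowest RSS)
    converged solution.  Solver failure and degenerate (variance-free) input
    yield ``valid=False`` rather than an exception; fewer than ``MIN_POINTS``
    distinct temperatures is an input error.
    """
    t = profile.temperatures_c
    y = profile.rel_abundance
    if np.unique(t).size < MIN_POINTS:
        raise InputError(
            f"need >= {MIN_POINTS} distinct temperatures, got {np.unique(t).size}"
        )
    fit = MeltFit(
        protein_id=profile.protein_id, condition=profile.condition, replicate=profile.replicate
    )
    bounds = ([1e-6, 1e-6, 0.0], [np.inf, 100.0, 1.0 - 1e-9])
    best = None
    for start in _initial_guesses(t, y):
        try:
            popt, _ = optimize.curve_fit(
                sigmoid_model, t, y, p0=start, bounds=bounds, max_nfev=max_nfev
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - sigmoid_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss < 1e-12:
            break
    if best is None:
        return fit
    (a, b, pl), rss = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit.a, fit.b, fit.plateau, fit.rss = float(a), float(b), float(pl), rss
    if ss_tot > 1e-12:
        fit.r_squared = 1.0 - rss / ss_tot
        fit.valid = True
    else:
        # flat profile: no melting transition to fit
        fit.r_squared = math.nan
        fit.valid = False
    window = (float(t[0]) - TM_EXTRAPOLATION_C, float(t[-1]) + TM_EXTRAPOLATION_C)
    fit.tm_c = compute_tm(fit.a, fit.b, fit.plateau, window=window)
    return fit


def curve_quality_filter(
    fit: MeltFit,
    r2_min: float = 0.8,
    plateau_max: float = 0.3,
) -> bool:
    """Validity criterion for a melting curve.

    A curve passes when the fit converged, explains the data well
    (R² >= ``r2_min``), denatures substantially (plateau < ``plateau_max``)
    and has a defined Tm.  Defaults follow common TPP practice and are
    configurable.
    """
    if not fit.valid or fit.tm_c is None:
        return False
    if not np.isfinite(fit.r_squared) or fit.r_squared < r2_min:
        return False
    return fit.plateau < plateau_max


# ---------------------------------------------------------------------------
# Table-level operations


def read_melt_table(path) -> pd.DataFrame:
    """Read a long-format melt table TSV (protein_id, condition, replicate,
    temperature_c, rel_abundance)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MELT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"melt table missing columns: {missing}")
    return df[MELT_TABLE_COLUMNS]


def iter_profiles(df: pd.DataFrame) -> Iterable[MeltProfile]:
    """Yield one :class:`MeltProfile` per (protein, condition, replicate) group."""
    for (pid, cond, rep), g in df.groupby(["protein_id", "condition", "replicate"], sort=True):
        g = g.sort_values("temperature_c")
        yield MeltProfile(
            protein_id=str(pid),
            condition=str(cond),
            replicate=int(rep),
            temperatures_c=g["temperature_c"].to_numpy(float),
            rel_abundance=g["rel_abundance"].to_numpy(float),
        )


def fit_all_profiles(
    df: pd.DataFrame,
    r2_min: float = 0.8,
    plateau_max: float = 0.3,
) -> pd.DataFrame:
    """Fit every profile of a long-format melt table.

    Returns one row per profile with parameters, RSS, R², Tm and the
    quality-filter verdict in ``passes_filter``.
    """
    rows = []
    for profile in iter_profiles(df):
        fit = fit_melting_curve(profile)
        rows.append(
            {
                "protein_id": fit.protein_id,
                "condition": fit.condition,
                "replicate": fit.replicate,
                "a": fit.a,
                "b": fit.b,
                "plateau": fit.plateau,
                "rss": fit.rss,
                "r_squared": fit.r_squared,
                "tm_c": fit.tm_c if fit.tm_c is not None else math.nan,
                "valid": fit.valid,
                "passes_filter": curve_quality_filter(fit, r2_min=r2_min, plateau_max=plateau_max),
            }
        )
    return pd.DataFrame(rows)


def write_fit_table(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)


def delta_tm(
    fits: pd.DataFrame,
    treatment: str = "treatment",
    vehicle: str = "vehicle",
) -> pd.DataFrame:
    """Per-protein, per-replicate thermal shift Tm(treatment) - Tm(vehicle).

    Rows where either condition's Tm is undefined (NaN) are omitted.
    """
    pivot = fits.pivot_table(
        index=["protein_id", "replicate"], columns="condition", values="tm_c", aggfunc="first"
    )
    if treatment not in pivot.columns or vehicle not in pivot.columns:
        return pd.DataFrame(columns=["protein_id", "replicate", "delta_tm_c"])
    out = (pivot[treatment] - pivot[vehicle]).dropna().rename("delta_tm_c").reset_index()
    return out


def replicate_tm_correlation(
    fits: pd.DataFrame,
    rep_a: int = 1,
    rep_b: int = 2,
    min_pairs: int = 3,
) -> dict[str, float]:
    """Pearson correlation of per-protein Tm between two replicates, per condition.

    Only proteins with a defined Tm in both replicates enter; fewer than
    ``min_pairs`` such proteins in a condition is a statistics error.
    """
    result: dict[str, float] = {}
    for cond, g in fits.groupby("condition"):
        pivot = g.pivot_table(
            index="protein_id", columns="replicate", values="tm_c", aggfunc="first"
        )
        if rep_a not in pivot.columns or rep_b not in pivot.columns:
            raise StatisticsError(f"condition {cond!r}: replicates {rep_a}/{rep_b} not both present")
        pairs = pivot[[rep_a, rep_b]].dropna()
        if len(pairs) < min_pairs:
            raise StatisticsError(
                f"condition {cond!r}: only {len(pairs)} proteins with Tm in both replicates"
            )
        r, _ = stats.pearsonr(pairs[rep_a], pairs[rep_b])
        result[str(cond)] = float(r)
    return result
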