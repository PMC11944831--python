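"""Compound-table filtering, deduplication and exact-mass validation.

Implements the identification filters applied to UPLC-Orbitrap component
tables (spectral-library score and sample/control abundance ratio), the
blank-control subtraction used for affinity-captured binding components,
cross-ionization-mode deduplication by compound name, and a small
monoisotopic-mass calculator that validates printed m/z values against the
[M+H]+ / [M-H]- adduct of the printed elemental formula by ppm error.

Thresholds are strict inequalities throughout ("over 80", "exceeding 20",
"must have exceeded 70").
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "theoretical_mz",
    "validate_table_mz",
    "ppm_error",
    "read_compound_table",
    "load_packaged_table",
    "filter_main_components",
    "filter_binding_components",
    "deduplicate_across_modes",
]

#: Monoisotopic atomic masses (Da) of the elements supported in formulas.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Mass of a proton (Da); the [M+H]+ / [M-H]- adduct delta.
PROTON_MASS = 1.007276

_ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    # formate adduct, common in negative ESI with a formic-acid mobile phase:
    # M + HCOOH - H(+)
    "[M+FA-H]-": 12.0 + 2 * 1.00782503 + 2 * 15.99491462 - PROTON_MASS,
}
_MODE_ADDUCT = {"positive": "[M+H]+", "negative": "[M-H]-"}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or unsupported elemental formula."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C27H32O14`` into element counts.

    Supports the elements in :data:`MONOISOTOPIC_MASS`; anything else, or a
    string that is not a plain element-count sequence, is a
    :class:`FormulaError` naming the offending token.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"unparseable token {s[pos:m.start()]!r} in {formula!r}")
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"unparseable trailing text {s[pos:]!r} in {formula!r}")
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map."""
    total = 0.0
    for elem, n in counts.items():
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"no monoisotopic mass for element {elem!r}")
        if n < 0:
            raise FormulaError(f"negative count for element {elem!r}")
        total += n * MONOISOTOPIC_MASS[elem]
    return total


def adduct_mz(mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct: ``[M+H]+`` or ``[M-H]-``."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    return mass + _ADDUCTS[adduct]


def theoretical_mz(formula: str, ion_mode: str) -> float:
    """Theoretical [M+H]+ (positive mode) or [M-H]- (negative mode) m/z of a formula."""
    if ion_mode not in _MODE_ADDUCT:
        raise ValueError(f"ion_mode must be 'positive' or 'negative', got {ion_mode!r}")
    return adduct_mz(monoisotopic_mass(parse_formula(formula)), _MODE_ADDUCT[ion_mode])


def validate_table_mz(records: pd.DataFrame) -> pd.DataFrame:
    """Theoretical adduct m/z and ppm error for every row of a compound table.

    The adduct comes from the row's ``adduct`` column when present (some
    compounds ionize as formate adducts in negative mode), otherwise from the
    mode default ([M+H]+ / [M-H]-).  Returns a copy with ``theoretical_mz``
    and ``ppm`` columns.
    """
    out = records.copy()
    theo = []
    for _, row in records.iterrows():
        adduct = row.get("adduct")
        if isinstance(adduct, str) and adduct.strip():
            mz = adduct_mz(monoisotopic_mass(parse_formula(row["formula"])), adduct.strip())
        else:
            mz = theoretical_mz(row["formula"], row["ion_mode"])
        theo.append(mz)
    out["theoretical_mz"] = theo
    out["ppm"] = [ppm_error(t, m) for t, m in zip(theo, records["mz"])]
    return out


def ppm_error(mz_a: float, mz_b: float) -> float:
    """Relative mass deviation |a - b| / b in parts per million."""
    if mz_a <= 0 or mz_b <= 0:
        raise ValueError("m/z values must be positive")
    return abs(mz_a - mz_b) / mz_b * 1e6


# ---------------------------------------------------------------------------
# Tables


def read_compound_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a compound table (TSV or CSV; ``#`` lines are comments)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


def load_packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables.

    ``name`` is one of ``table1_negative``, ``table2_positive``,
    ``table3_binding`` (TSV) or ``table4_docking`` (CSV).
    """
    pkg = resources.files("tppkit") / "data"
    for ext, sep in ((".tsv", "\t"), (".csv", ",")):
        candidate = pkg / f"{name}{ext}"
        if candidate.is_file():
            with resources.as_file(candidate) as p:
                return pd.read_csv(p, sep=sep, comment="#")
    raise FileNotFoundError(f"no packaged table named {name!r}")


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name)).strip().casefold()


def filter_main_components(
    records: pd.DataFrame,
    score_min: float = 80.0,
    ratio_min: float = 20.0,
) -> pd.DataFrame:
    """Keep rows with spectral-library score strictly over ``score_min`` and
    sample/control abundance ratio strictly exceeding ``ratio_min``."""
    if "mzvault_score" not in records.columns:
        raise ValueError("records must carry an 'mzvault_score' column")
    if "sample_control_ratio" not in records.columns or records["sample_control_ratio"].isna().any():
        raise ValueError("records must carry a complete 'sample_control_ratio' column")
    keep = (records["mzvault_score"] > score_min) & (records["sample_control_ratio"] > ratio_min)
    return records.loc[keep].copy()


def filter_binding_components(
    records_sample: pd.DataFrame,
    records_blank: pd.DataFrame | None = None,
    score_min: float = 70.0,
) -> pd.DataFrame:
    """Keep affinity-captured rows with score strictly over ``score_min`` that
    are absent (by normalized name) from the blank-control run."""
    if "mzvault_score" in records_sample.columns:
        keep = records_sample["mzvault_score"] > score_min
    else:
        keep = pd.Series(True, index=records_sample.index)
    if records_blank is not None and len(records_blank):
        blank_names = {_normalize_name(n) for n in records_blank["name"]}
        keep &= ~records_sample["name"].map(lambda n: _normalize_name(n) in blank_names)
    return records_sample.loc[keep].copy()


def deduplicate_across_modes(
    neg_records: pd.DataFrame,
    pos_records: pd.DataFrame,
) -> pd.DataFrame:
    """Union of the two ionization modes keyed by normalized compound name.

    Returns one row per unique compound with per-mode provenance: the
    observed m/z in each mode (NaN when not observed) and the set of modes.
    Commutative in its two arguments and idempotent.
    """
    frames = []
    for df, mode in ((neg_records, "negative"), (pos_records, "positive")):
        sub = df.copy()
        if "ion_mode" not in sub.columns:
            sub["ion_mode"] = mode
        frames.append(sub)
    both = pd.concat(frames, ignore_index=True)
    both["_key"] = both["name"].map(_normalize_name)

    rows = []
    for key, g in both.groupby("_key", sort=True):
        neg = g[g["ion_mode"] == "negative"]
        pos = g[g["ion_mode"] == "positive"]
        rows.append(
            {
                "name": g["name"].iloc[0],
                "formula": g["formula"].iloc[0] if "formula" in g else None,
                "modes": ",".join(sorted(g["ion_mode"].unique())),
                "mz_negative": float(neg["mz"].iloc[0]) if len(neg) and "mz" in g else np.nan,
                "mz_positive": float(pos["mz"].iloc[0]) if len(pos) and "mz" in g else np.nan,
            }
        )
    return pd.DataFrame(rows)
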