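"""Zonal electron-microprobe (WDS-EMPA) table handling.

Points are oxide-wt% analyses grouped by bone zone — outer cortical (OC),
mid cortical (MC), inner cortical (IC) and around vascular/Haversian canals
(HC).  Processing follows the published data rules: analyte values below
their detection limit are entered as exactly 0.00, and whole points whose
analytical total falls below 50 wt% (mislocated beam) are removed with a
QC log entry.  Summaries report n, mean, 2x standard error and the
coefficient of variation per (analyte, zone, PMI, state) cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .errors import ConfigurationError, FormatError

log = logging.getLogger(__name__)

ZONES = ("OC", "MC", "IC", "HC")
STATES = ("unburnt", "burnt")
SCHEMA = ["sample_id", "state", "pmi_days", "zone", *chem.ANALYTES, "total"]

#: conservative placeholder detection limits (oxide wt%).  The instrument's
#: published per-run limits should replace these in config for real data.
DEFAULT_DETECTION_LIMITS: dict[str, float] = {
    "P2O5": 0.05, "CaO": 0.05,
    "Al2O3": 0.01, "Na2O": 0.01, "SiO2": 0.01, "K2O": 0.01,
    "Cl": 0.01, "MgO": 0.01, "SrO": 0.01, "FeO": 0.01, "MnO": 0.01,
}

#: QC threshold: points whose analytical total is below this are removed.
LOW_TOTAL_THRESHOLD = 50.0


@dataclass(frozen=True)
class DetectionLimits:
    """Per-analyte detection limits in oxide wt%."""

    limits: Mapping[str, float]

    def __post_init__(self) -> None:
        for analyte, v in self.limits.items():
            if analyte not in chem.ANALYTES:
                raise ConfigurationError(f"detection limit for unknown analyte {analyte!r}")
            if v <= 0:
                raise ConfigurationError(f"detection limit for {analyte} must be > 0")
        missing = [a for a in chem.ANALYTES if a not in self.limits]
        if missing:
            raise ConfigurationError(f"detection limits missing analytes: {missing}")

    def __getitem__(self, analyte: str) -> float:
        return float(self.limits[analyte])

    def elemental(self, analyte: str) -> float:
        """The limit expressed on the elemental-wt% scale."""
        return self[analyte] * chem.element_fraction(analyte)

    @classmethod
    def default(cls) -> "DetectionLimits":
        return cls(dict(DEFAULT_DETECTION_LIMITS))


@dataclass
class EmpaTable:
    """QC'd point analyses plus the log of removed points."""

    points: pd.DataFrame
    qc_log: list[dict] = field(default_factory=list)
    below_dl: pd.DataFrame | None = None  # boolean flags, same index as points

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_removed(self) -> int:
        return len(self.qc_log)


def load_empa_csv(source) -> EmpaTable:
    """Load and validate a point table against the documented schema."""
    df = pd.read_csv(source)
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise FormatError(f"EMPA CSV missing column(s): {missing}")
    df = df[SCHEMA].copy()
    bad_zone = set(df["zone"]) - set(ZONES)
    if bad_zone:
        raise FormatError(f"unknown zone code(s): {sorted(bad_zone)}; expected {ZONES}")
    bad_state = set(df["state"]) - set(STATES)
    if bad_state:
        raise FormatError(f"unknown state(s): {sorted(bad_state)}; expected {STATES}")
    numeric = [*chem.ANALYTES, "total"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()[:5]
            raise FormatError(f"column {col!r}: missing/non-numeric values at rows {rows}")
        if (vals < 0).any():
            raise FormatError(f"column {col!r}: negative wt% values")
        df[col] = vals
    df["pmi_days"] = pd.to_numeric(df["pmi_days"], errors="raise").astype(int)
    return EmpaTable(points=df.reset_index(drop=True))


def clean_empa(table: EmpaTable, limits: DetectionLimits | None = None) -> EmpaTable:
    """Censor below-detection values to 0.00, then drop low-total points.

    Censoring happens first; the <50 wt% filter is applied to the original
    analytical total so a censored point is judged by what the instrument
    actually measured.  Retained + removed always equals the input count.
    """
    if limits is None:
        limits = DetectionLimits.default()
    df = table.points.copy()
    flags = pd.DataFrame(False, index=df.index, columns=list(chem.ANALYTES))
    for analyte in chem.ANALYTES:
        below = df[analyte] < limits[analyte]
        flags[analyte] = below
        df.loc[below, analyte] = 0.00
    keep = df["total"] >= LOW_TOTAL_THRESHOLD
    qc_log = list(table.qc_log)
    for idx in df.index[~keep]:
        qc_log.append({
            "sample_id": df.at[idx, "sample_id"],
            "zone": df.at[idx, "zone"],
            "total": float(df.at[idx, "total"]),
            "reason": f"analytical total < {LOW_TOTAL_THRESHOLD:g} wt%",
        })
    kept = df[keep].reset_index(drop=True)
    return EmpaTable(points=kept, qc_log=qc_log,
                     below_dl=flags[keep].reset_index(drop=True))


def oxide_to_element(data: EmpaTable | pd.DataFrame) -> pd.DataFrame:
    """Convert oxide-wt% columns to elemental wt% (Cl passes through)."""
    df = data.points if isinstance(data, EmpaTable) else data
    out = df[[c for c in ("sample_id", "state", "pmi_days", "zone") if c in df.columns]].copy()
    for oxide in chem.ANALYTES:
        if oxide not in df.columns:
            raise ConfigurationError(f"missing analyte column {oxide!r}")
        out[chem.element_for(oxide)] = df[oxide] * chem.element_fraction(oxide)
    if "total" in df.columns:
        out["total"] = df["total"]
    return out


def element_to_oxide(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`oxide_to_element` (on the analyte columns)."""
    out = df[[c for c in ("sample_id", "state", "pmi_days", "zone") if c in df.columns]].copy()
    for oxide in chem.ANALYTES:
        el = chem.element_for(oxide)
        if el not in df.columns:
            raise ConfigurationError(f"missing element column {el!r}")
        out[oxide] = df[el] / chem.element_fraction(oxide)
    if "total" in df.columns:
        out["total"] = df["total"]
    return out


def ca_p_molar_ratio(data: EmpaTable | pd.DataFrame | Mapping[str, float]):
    """Molar Ca/P per point: (CaO/M_CaO) / (2 * P2O5/M_P2O5).

    P2O5 = 0 yields not-applicable (nan) with a warning; CaO = 0 yields 0.
    The ratio is algebraically identical computed from oxide or elemental
    weights.
    """
    if isinstance(data, Mapping) and not isinstance(data, pd.DataFrame):
        cao = np.asarray([data["CaO"]], dtype=float)
        p2o5 = np.asarray([data["P2O5"]], dtype=float)
        scalar = True
    else:
        df = data.points if isinstance(data, EmpaTable) else data
        cao = df["CaO"].to_numpy(dtype=float)
        p2o5 = df["P2O5"].to_numpy(dtype=float)
        scalar = False
    m_cao = chem.oxide_molar_mass("CaO")
    m_p2o5 = chem.oxide_molar_mass("P2O5")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (cao / m_cao) / (2.0 * p2o5 / m_p2o5)
    zero_p = p2o5 == 0
    if np.any(zero_p):
        warnings.warn("Ca/P not-applicable where P2O5 = 0", stacklevel=2)
        ratio = np.where(zero_p, np.nan, ratio)
    ratio = np.where((cao == 0) & ~zero_p, 0.0, ratio)
    return float(ratio[0]) if scalar else ratio


def summarize(
    table: EmpaTable | pd.DataFrame,
    group_keys: Sequence[str] = ("state", "pmi_days", "zone"),
    elemental: bool = True,
) -> pd.DataFrame:
    """Per-cell n, mean, 2SE and CV for every analyte.

    SE = SD/sqrt(n) with the n-1 SD; cells with n = 1 have nan SE, and CV is
    nan where the mean is 0.  Returns a long table with one row per
    (analyte x cell).
    """
    df = table.points if isinstance(table, EmpaTable) else table
    if elemental:
        df = oxide_to_element(df)
        analytes = list(chem.ELEMENTS)
    else:
        analytes = list(chem.ANALYTES)
    rows = []
    if df.empty:
        return pd.DataFrame(columns=["analyte", *group_keys, "n", "mean", "se2", "cv"])
    for keys, sub in df.groupby(list(group_keys), observed=True, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for analyte in analytes:
            vals = sub[analyte].to_numpy(dtype=float)
            n = vals.size
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
            rows.append({
                "analyte": analyte,
                **dict(zip(group_keys, keys)),
                "n": n,
                "mean": mean,
                "se2": 2.0 * sd / np.sqrt(n) if n > 1 else np.nan,
                "cv": sd / mean if n > 1 and mean != 0 else np.nan,
            })
    return pd.DataFrame(rows)


def write_qc_log(table: EmpaTable, path) -> None:
    import json

    path = Path(path)
    path.write_text(json.dumps(table.qc_log, indent=2, default=str) + "\n")
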