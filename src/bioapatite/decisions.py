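"""Interpretive rules: cremation-state classification, heat-marker
temperature banding, and the potassium-threshold inference of how long a
body decomposed before being burnt.

The potassium rule rests on the depletion of extracellular-fluid potassium
during decomposition: burnt-fresh bone keeps K >= 0.20 wt% while inner
(IC) and mid-cortical (MC) K below 0.07 +/- 0.01 wt% indicates at least
~three months of surface decomposition before burning, and mid-cortical K
below the detection limit indicates more than a year.  Outer-cortical (OC)
values never drive the category because soil uptake can replenish K there;
all categorical outputs carry the caveat that burial slows dehydration and
therefore stretches these time bands.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from . import empa
from .errors import IndeterminateInputError, RuleInapplicableError
from .spectra import FtirRatioRecord, MarkerReport
from .stats import LdaResult

BURIAL_CAVEAT = ("bones were modelled as surface-exposed; burial slows dehydration, "
                 "so time bands stretch for buried remains")
OC_CAVEAT = ("outer-cortical K excluded from the decision: soil uptake can "
             "replenish potassium in the OC zone")
FRESH_FLOOR_CAVEAT = ("the >= 0.20 wt% fresh-burnt floor is an inference from the "
                      "day-0 observations, not an explicitly stated rule")


class PmiCategory(str, Enum):
    PERI_MORTEM = "peri-mortem burn plausible (<= ~2 weeks)"
    DELAYED = "delayed burn (>= ~3 months surface exposure)"
    LONG_DELAY = "long delay (>= 1 year; K below detection in MC)"
    BORDERLINE = "borderline"
    INDETERMINATE = "indeterminate"


@dataclass
class BurnAssessment:
    label: str  # unburnt | burnt
    confidence: float
    evidence: dict[str, float] = field(default_factory=dict)
    method: str = "rule"

    def to_json(self) -> str:
        return json.dumps({"label": self.label, "confidence": self.confidence,
                           "method": self.method, "evidence": self.evidence},
                          sort_keys=True)


@dataclass
class PmiAssessment:
    category: PmiCategory
    threshold: float
    band: float
    zone_values: dict[str, float]
    detection_limit: float
    caveats: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "category": self.category.value,
            "threshold_wt_pct": self.threshold,
            "band_wt_pct": self.band,
            "zone_values_wt_pct": self.zone_values,
            "detection_limit_wt_pct": self.detection_limit,
            "caveats": self.caveats,
            "evidence": self.evidence,
        }, sort_keys=True)


@dataclass
class HeatAssessment:
    statements: list[str]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# burnt/unburnt state
# ---------------------------------------------------------------------------

def classify_state(
    record: FtirRatioRecord,
    model: LdaResult | None = None,
    feature_names: list[str] | None = None,
    cn_p_floor: float = 0.02,
    irsf_cut: float = 3.8,
) -> BurnAssessment:
    """Label a spectrum burnt or unburnt.

    With a fitted LDA the prediction and its posterior are returned; the
    rule-based fallback declares burnt when cyanamide/phosphate exceeds a
    floor (cyanamide only forms on burning under reducing conditions) or
    the crystallinity index exceeds a cut, with confidence from the margin.
    """
    discriminators = {k: record.values.get(k, math.nan) for k in ("C/P", "PHT", "CN/P")}
    if all(not np.isfinite(v) for v in discriminators.values()):
        raise IndeterminateInputError("C/P, PHT and CN/P are all not-applicable")
    if model is not None:
        names = feature_names or list(model.coefficients.index)
        x = np.array([[record.values.get(n, math.nan) for n in names]])
        if np.any(~np.isfinite(x)):
            missing = [n for n in names if not np.isfinite(record.values.get(n, math.nan))]
            raise IndeterminateInputError(f"LDA features not-applicable: {missing}")
        post = model.model.predict_proba(x)[0]
        idx = int(np.argmax(post))
        return BurnAssessment(
            label=str(model.classes[idx]),
            confidence=float(post[idx]),
            evidence={n: float(v) for n, v in zip(names, x[0])},
            method="lda",
        )
    cn_p = discriminators["CN/P"]
    irsf = record.values.get("IRSF", math.nan)
    cn_margin = (cn_p - cn_p_floor) / cn_p_floor if np.isfinite(cn_p) else -1.0
    irsf_margin = (irsf - irsf_cut) / irsf_cut if np.isfinite(irsf) else -1.0
    burnt = cn_margin > 0 or irsf_margin > 0
    margin = max(cn_margin, irsf_margin)
    confidence = float(1.0 / (1.0 + math.exp(-4.0 * abs(margin))))
    evidence = {"CN/P": cn_p, "IRSF": irsf,
                "cn_p_floor": cn_p_floor, "irsf_cut": irsf_cut}
    return BurnAssessment(label="burnt" if burnt else "unburnt",
                          confidence=confidence, evidence=evidence)


# ---------------------------------------------------------------------------
# heat markers
# ---------------------------------------------------------------------------

def assess_heat_markers(markers: MarkerReport, state: str) -> HeatAssessment:
    """Temperature-band statement from the categorical markers.

    Both beta-TCP signals (1123 cm^-1 peak AND 547 cm^-1 shoulder) are
    required for a >700 degC claim; the 1123 peak alone is ambiguous (it can
    reflect Mg substitution or a spectral shift).  An OH-Cl peak indicates
    chlorine substitution into apatite above ~600 degC.  In unburnt bone the
    547 shoulder means Mg substitution, so the rule refuses to run.
    """
    if state != "burnt":
        raise RuleInapplicableError(
            "heat-marker banding is defined for burnt bone only "
            "(in unburnt bone the 547 cm^-1 shoulder indicates Mg substitution)"
        )
    statements: list[str] = []
    notes: list[str] = []
    if markers.btcp_peak_1123 and markers.shoulder_547:
        statements.append("> 700 °C reached (beta-TCP: 1123 cm^-1 peak with 547 cm^-1 shoulder)")
    elif markers.btcp_peak_1123 and not markers.shoulder_547:
        notes.append("1123 cm^-1 peak present without the 547 cm^-1 shoulder: "
                     "ambiguous — may be a spectral shift or Mg substitution "
                     "rather than beta-TCP; no > 700 °C claim")
    if markers.oh_cl_peak:
        statements.append("> 600 °C reached (OH-Cl substitution peak)")
    if not statements and not notes:
        statements.append("no high-temperature marker")
    elif not statements:
        statements.append("no high-temperature marker confirmed")
    return HeatAssessment(statements=statements, notes=notes)


# ---------------------------------------------------------------------------
# potassium PMI rule
# ---------------------------------------------------------------------------

def k_pmi_rule(
    zone_k: Mapping[str, float],
    state: str,
    limits: empa.DetectionLimits | None = None,
    threshold: float = 0.07,
    band: float = 0.01,
    fresh_floor: float = 0.20,
) -> PmiAssessment:
    """Categorise PMI-before-burning from zonal elemental potassium (wt%).

    ``zone_k`` maps zone codes to elemental K wt% (OC values, if given, are
    reported but never decisive).  Branches, in order: MC below detection ->
    long delay (> 1 year); IC and MC both < threshold - band -> delayed burn
    (>= ~3 months); both >= fresh_floor -> peri-mortem plausible; either
    inside [threshold - band, threshold + band] -> borderline; otherwise
    indeterminate.
    """
    if state != "burnt":
        raise RuleInapplicableError("the potassium PMI rule is defined for burnt bone only")
    if limits is None:
        limits = empa.DetectionLimits.default()
    dl = limits.elemental("K2O")
    ic = zone_k.get("IC")
    mc = zone_k.get("MC")
    if ic is None or mc is None or not np.isfinite(ic) or not np.isfinite(mc):
        raise IndeterminateInputError("IC and MC potassium values are required")
    caveats = [BURIAL_CAVEAT]
    if "OC" in zone_k:
        caveats.append(OC_CAVEAT)
    lo, hi = threshold - band, threshold + band
    evidence = {"IC_K": float(ic), "MC_K": float(mc),
                "threshold": threshold, "band": band,
                "fresh_floor": fresh_floor, "detection_limit": dl}
    if "HC" in zone_k:
        evidence["HC_K_supporting"] = float(zone_k["HC"])
    if "OC" in zone_k:
        evidence["OC_K_reported_only"] = float(zone_k["OC"])

    if mc < dl:
        category = PmiCategory.LONG_DELAY
    elif ic < lo and mc < lo:
        category = PmiCategory.DELAYED
    elif ic >= fresh_floor and mc >= fresh_floor:
        category = PmiCategory.PERI_MORTEM
        caveats.append(FRESH_FLOOR_CAVEAT)
    elif lo <= ic <= hi or lo <= mc <= hi:
        category = PmiCategory.BORDERLINE
    else:
        category = PmiCategory.INDETERMINATE
    return PmiAssessment(
        category=category, threshold=threshold, band=band,
        zone_values={z: float(v) for z, v in zone_k.items()},
        detection_limit=dl, caveats=caveats, evidence=evidence,
    )


def specimen_zone_k(table: empa.EmpaTable | pd.DataFrame) -> pd.DataFrame:
    """Per-specimen mean elemental K by zone (wide: one row per specimen).

    Input should already be cleaned (censored + QC-filtered).
    """
    df = table.points if isinstance(table, empa.EmpaTable) else table
    el = empa.oxide_to_element(df)
    wide = (el.groupby(["sample_id", "state", "pmi_days", "zone"], observed=True)["K"]
              .mean().unstack("zone").reset_index())
    wide.columns.name = None
    return wide


def assess_study(table: empa.EmpaTable | pd.DataFrame,
                 limits: empa.DetectionLimits | None = None,
                 threshold: float = 0.07, band: float = 0.01) -> pd.DataFrame:
    """Run the potassium rule over every burnt specimen in a cleaned table."""
    wide = specimen_zone_k(table)
    rows = []
    for _, row in wide.iterrows():
        if row["state"] != "burnt":
            continue
        zone_k = {z: row[z] for z in ("OC", "MC", "IC", "HC") if z in row and np.isfinite(row[z])}
        assessment = k_pmi_rule(zone_k, "burnt", limits=limits,
                                threshold=threshold, band=band)
        rows.append({
            "sample_id": row["sample_id"],
            "pmi_days": row["pmi_days"],
            "category": assessment.category.value,
            "IC_K": zone_k.get("IC"), "MC_K": zone_k.get("MC"),
        })
    return pd.DataFrame(rows)
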