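"""End-to-end orchestration shared by the CLI, the numbered analysis
scripts and the acceptance harness.

Each stage is a pure function from artifacts to artifacts so the whole run
is reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decisions, empa, spectra, stats, synthetic
from .config import RunConfig

#: ratios finite and applicable in both states — the cross-state feature set.
STATE_FEATURES = ["IRSF", "C/P", "BPI", "CN/P", "CO/CO3", "PHT"]


def simulate_stage(cfg: RunConfig, seed: int | None = None) -> synthetic.StudyBundle:
    """Generate the default (publication-shaped) synthetic study."""
    sim = cfg.simulate
    trends = synthetic.make_default_trends(
        oc_uptake=sim.oc_uptake,
        extra_peak_absent_34d=sim.extra_peak_absent_34d,
        include_btcp=sim.include_btcp,
    )
    design = synthetic.published_design(
        points_per_zone=sim.points_per_zone,
        absorbance_noise_sd=sim.absorbance_noise_sd,
        low_total_fraction=sim.low_total_fraction,
        seed=cfg.seed if seed is None else seed,
    )
    return synthetic.simulate_study(design, trends)


def ftir_stage(spectra_list: list[spectra.Spectrum], cfg: RunConfig) -> pd.DataFrame:
    """Baseline-correct every spectrum and evaluate ratios + markers."""
    battery = cfg.battery()
    mk = cfg.markers
    rows = []
    for spec in spectra_list:
        corrected = spectra.baseline_correct(spec, anchors=cfg.anchors)
        record = spectra.compute_ratios(corrected, battery)
        record.markers = spectra.detect_markers(
            corrected,
            btcp_center=mk.btcp_center, btcp_tol=mk.btcp_tol,
            shoulder_center=mk.shoulder_center, shoulder_tol=mk.shoulder_tol,
            extra_band=tuple(mk.extra_band),
            oh_cl_center=mk.oh_cl_center, oh_cl_tol=mk.oh_cl_tol,
            prominence_floor=mk.prominence_floor,
        )
        rows.append(record.to_row())
    return pd.DataFrame(rows)


def empa_stage(table: empa.EmpaTable, cfg: RunConfig):
    """Censor, QC-filter and summarise the microprobe table."""
    cleaned = empa.clean_empa(table, cfg.limits())
    summary = empa.summarize(cleaned)
    return cleaned, summary


@dataclass
class StatsArtifacts:
    ftir_regressions: pd.DataFrame
    empa_regressions: pd.DataFrame
    ftir_pca: stats.PcaResult
    empa_pca: stats.PcaResult
    ftir_lda: stats.LdaResult
    empa_lda: stats.LdaResult
    ftir_manova: dict[str, stats.ManovaResult] = field(default_factory=dict)
    empa_manova: dict[str, stats.ManovaResult] = field(default_factory=dict)


def _regression_table(df: pd.DataFrame, params: list[str], cfg: RunConfig,
                      by_state: bool = True) -> pd.DataFrame:
    rows = []
    states = sorted(df["state"].unique()) if by_state else [None]
    for state in states:
        sub = df if state is None else df[df["state"] == state]
        for param in params:
            y = sub[param].to_numpy(dtype=float)
            x = sub["pmi_days"].to_numpy(dtype=float)
            keep = np.isfinite(y)
            if keep.sum() < 3 or np.unique(x[keep]).size < 2:
                continue
            res = stats.linregress_vs_pmi(
                x[keep], y[keep],
                alternative=cfg.stats.sidedness, unit=cfg.stats.regression_unit,
            )
            rows.append({"state": state, "parameter": param, "slope": res.slope,
                         "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def stats_stage(ftir_df: pd.DataFrame, cleaned: empa.EmpaTable, cfg: RunConfig) -> StatsArtifacts:
    """The full battery on both data streams."""
    ftir_regs = _regression_table(ftir_df, STATE_FEATURES, cfg)

    elemental = empa.oxide_to_element(cleaned)
    elements = [c for c in elemental.columns
                if c not in ("sample_id", "state", "pmi_days", "zone", "total")]
    empa_regs = _regression_table(elemental, elements, cfg)

    ftir_X = ftir_df[STATE_FEATURES].astype(float)
    ftir_scaled = stats.zscore_scale(ftir_X)
    ftir_pca = stats.pca(ftir_scaled)
    ftir_lda = stats.lda(ftir_scaled, ftir_df["state"].to_numpy())

    empa_X = elemental[elements].astype(float)
    empa_scaled = stats.zscore_scale(empa_X)
    empa_pca = stats.pca(empa_scaled)
    empa_lda = stats.lda(empa_scaled, elemental["state"].to_numpy())

    art = StatsArtifacts(
        ftir_regressions=ftir_regs, empa_regressions=empa_regs,
        ftir_pca=ftir_pca, empa_pca=empa_pca,
        ftir_lda=ftir_lda, empa_lda=empa_lda,
    )
    # MANOVA by state and (within state) by PMI group
    art.ftir_manova["state"] = stats.manova_with_mct(
        ftir_scaled, ftir_df["state"].to_numpy(),
        alpha=cfg.stats.alpha, method=cfg.stats.mct_method)
    art.empa_manova["state"] = stats.manova_with_mct(
        empa_scaled, elemental["state"].to_numpy(),
        alpha=cfg.stats.alpha, method=cfg.stats.mct_method)
    for state in ("unburnt", "burnt"):
        m = ftir_df["state"] == state
        if m.sum() > len(STATE_FEATURES) + ftir_df.loc[m, "pmi_days"].nunique():
            art.ftir_manova[f"pmi_{state}"] = stats.manova_with_mct(
                stats.zscore_scale(ftir_X[m.to_numpy()]),
                ftir_df.loc[m, "pmi_days"].to_numpy(),
                alpha=cfg.stats.alpha, method=cfg.stats.mct_method)
    return art


@dataclass
class ClassifyArtifacts:
    state_assessments: pd.DataFrame
    pmi_assessments: pd.DataFrame
    heat_assessments: list[dict]


def classify_stage(ftir_df: pd.DataFrame, cleaned: empa.EmpaTable,
                   cfg: RunConfig, lda_model: stats.LdaResult | None = None) -> ClassifyArtifacts:
    """Decision rules over every specimen.

    When an LDA fitted on the scaled feature matrix is supplied, state
    classification uses it through standardised features; otherwise the
    rule-based fallback runs on raw ratio values.
    """
    dec = cfg.decisions
    state_rows = []
    heat = []
    # refit an LDA on raw (unscaled) features so single records can be scored
    raw_lda = None
    if lda_model is not None:
        raw_lda = stats.lda(ftir_df[STATE_FEATURES].astype(float),
                            ftir_df["state"].to_numpy())
    for _, row in ftir_df.iterrows():
        record = spectra.FtirRatioRecord(
            sample_id=row["sample_id"], state=row["state"],
            pmi_days=row["pmi_days"],
            values={k: float(row[k]) if pd.notna(row[k]) else math.nan
                    for k in STATE_FEATURES},
            applicable={k: bool(pd.notna(row[k])) for k in STATE_FEATURES},
        )
        assessment = decisions.classify_state(
            record, model=raw_lda, feature_names=STATE_FEATURES if raw_lda else None,
            cn_p_floor=dec.cn_p_floor, irsf_cut=dec.irsf_cut,
        )
        state_rows.append({
            "sample_id": row["sample_id"], "true_state": row["state"],
            "predicted_state": assessment.label,
            "confidence": assessment.confidence, "method": assessment.method,
        })
        if assessment.label == "burnt":
            markers = spectra.MarkerReport(
                btcp_peak_1123=bool(row.get("btcp_peak_1123", False)),
                shoulder_547=bool(row.get("shoulder_547", False)),
                oh_cl_peak=bool(row.get("oh_cl_peak", False)),
            )
            ha = decisions.assess_heat_markers(markers, "burnt")
            heat.append({"sample_id": row["sample_id"],
                         "statements": ha.statements, "notes": ha.notes})
    pmi_df = decisions.assess_study(
        cleaned, limits=cfg.limits(),
        threshold=dec.k_threshold, band=dec.k_band,
    )
    return ClassifyArtifacts(
        state_assessments=pd.DataFrame(state_rows),
        pmi_assessments=pmi_df, heat_assessments=heat,
    )
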