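"""Structured report assembly: JSON + markdown, deterministic by content.

Sections mirror the analysis structure: FT-IR ratios per group, EMPA zone
summaries, the regression table, multivariate results, and decision
outcomes with their caveats.  Timestamps never enter report content so the
same artifacts always hash identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _df_section(title: str, df: pd.DataFrame, max_rows: int = 40) -> str:
    body = df.head(max_rows).to_markdown(index=False, floatfmt=".4g")
    extra = f"\n\n({len(df) - max_rows} further rows omitted)" if len(df) > max_rows else ""
    return f"## {title}\n\n{body}{extra}\n"


def write_report(artifacts: dict, out_dir) -> dict:
    """Collate stage outputs into ``report.json`` and ``report.md``.

    ``artifacts`` may hold any subset of the keys: ``ftir`` (ratio table),
    ``zone_summary``, ``regressions`` (dict of tables), ``multivariate``
    (dict), ``decisions`` (dict of tables/lists).  At least one must be
    present.
    """
    if not artifacts:
        raise ValueError("write_report needs at least one stage output")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload: dict = {}
    md: list[str] = ["# Bone bioapatite analysis report\n"]

    if "ftir" in artifacts:
        df = artifacts["ftir"]
        payload["ftir"] = json.loads(df.to_json(orient="records"))
        group_cols = [c for c in ("state", "pmi_days") if c in df.columns]
        numeric = df.select_dtypes("number").columns.difference(["pmi_days"])
        if group_cols:
            means = df.groupby(group_cols, observed=True)[list(numeric)].mean().reset_index()
            md.append(_df_section("FT-IR ratio means by group", means))
    if "zone_summary" in artifacts:
        df = artifacts["zone_summary"]
        payload["zone_summary"] = json.loads(df.to_json(orient="records"))
        md.append(_df_section("EMPA zone summary (elemental wt%)", df))
    if "regressions" in artifacts:
        payload["regressions"] = {}
        for name, df in artifacts["regressions"].items():
            payload["regressions"][name] = json.loads(df.to_json(orient="records"))
            md.append(_df_section(f"Linear regression vs PMI — {name}", df))
    if "multivariate" in artifacts:
        payload["multivariate"] = artifacts["multivariate"]
        md.append("## Multivariate results\n\n```json\n"
                  + json.dumps(artifacts["multivariate"], indent=2, sort_keys=True, default=str)
                  + "\n```\n")
    if "decisions" in artifacts:
        payload["decisions"] = {}
        for name, obj in artifacts["decisions"].items():
            if isinstance(obj, pd.DataFrame):
                payload["decisions"][name] = json.loads(obj.to_json(orient="records"))
                md.append(_df_section(f"Decisions — {name}", obj))
            else:
                payload["decisions"][name] = obj
                md.append(f"## Decisions — {name}\n\n```json\n"
                          + json.dumps(obj, indent=2, sort_keys=True, default=str)
                          + "\n```\n")

    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True,
                                                default=str) + "\n")
    (out / "report.md").write_text("\n".join(md) + "\n")
    return payload
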