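"""Collate every stage artifact into one structured report
(results/report.json + results/report.md)."""

import argparse
import json
from pathlib import Path

import pandas as pd

from bioapatite import report as report_mod


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out

    artifacts: dict = {}
    if (out / "ftir_ratios.csv").exists():
        artifacts["ftir"] = pd.read_csv(out / "ftir_ratios.csv")
    if (out / "zone_summary.csv").exists():
        artifacts["zone_summary"] = pd.read_csv(out / "zone_summary.csv")
    regs = {name: pd.read_csv(out / f"{name}.csv")
            for name in ("ftir_regressions", "empa_regressions")
            if (out / f"{name}.csv").exists()}
    if regs:
        artifacts["regressions"] = regs
    if (out / "multivariate.json").exists():
        artifacts["multivariate"] = json.loads((out / "multivariate.json").read_text())
    dec = {name: pd.read_csv(out / f"{name}.csv")
           for name in ("state_assessments", "pmi_assessments")
           if (out / f"{name}.csv").exists()}
    if (out / "heat_assessments.json").exists():
        dec["heat_assessments"] = json.loads((out / "heat_assessments.json").read_text())
    if dec:
        artifacts["decisions"] = dec

    payload = report_mod.write_report(artifacts, out)
    print(f"report with sections {sorted(payload)} -> {out / 'report.md'}")


if __name__ == "__main__":
    main()
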