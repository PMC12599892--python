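"""Longitudinal statistics over the measured (not ground-truth) values.

Assembles study tables from the OCE and Brillouin measurement outputs,
runs Kruskal-Wallis across days within each (group, condition),
Mann-Whitney U between conditions at each (group, day), and the
treated/control normalization that summarizes drug effect per group.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from spheromech import io, study


def to_study_table(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    table = df.rename(columns={metric: "value"})[
        ["group", "condition", "day", "replicate"]
    ].assign(metric=metric, value=df[metric])
    return study.validate_study_table(table)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--resultsdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    inputs = {
        "wave_speed_mps": pd.read_csv(args.resultsdir / "oce_speeds.csv"),
        "brillouin_shift_ghz": pd.read_csv(args.resultsdir / "brillouin_shifts.csv"),
    }
    report_all = {}
    norm_tables = []
    for metric, df in inputs.items():
        table = to_study_table(df, metric)
        io.save_study_csv(table, args.resultsdir / f"study_table_{metric}.csv")
        report = study.summarize_study(table)
        report_all[metric] = report
        norm = study.normalize_treated_to_control(table, metric)
        norm_tables.append(norm)

        print(f"\n=== {metric} ===")
        for r in report["mann_whitney"]:
            if r["day"] == 7:
                flag = "significant" if r["significant"] else "n.s."
                print(f"  day 7 {r['group']:>5} control vs treated: U={r['statistic']:.0f} "
                      f"p={r['p_value']:.3f} ({r['method']}, {flag})")
        d7 = norm[norm.day == 7].set_index("group")["ratio"]
        print(f"  day-7 treated/control ratios: LN229 {d7['LN229']:.2f} < "
              f"CO {d7['CO']:.2f} < HA {d7['HA']:.2f}")

    pd.concat(norm_tables).to_csv(args.resultsdir / "normalized_summary.csv", index=False)
    (args.resultsdir / "study_report.json").write_text(json.dumps(report_all, indent=2) + "\n")
    print(f"\nwrote {args.resultsdir / 'study_report.json'} and normalized_summary.csv")


if __name__ == "__main__":
    main()
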