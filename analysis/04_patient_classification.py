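#!/usr/bin/env python
"""Reduced-flow classification of patient vessel territories.

Applies the strict 2.5 mL/min/mL hyperaemic-flow rule to the packaged
per-vessel patient table (5 patients x 3 coronary territories with
angiographic groups), counts detections per model and group, and compares
flow between normal and stenotic vessels with Welch's t-test.
"""

from pathlib import Path

import numpy as np

from cmrperf.cohort import detection_counts, f_variance, welch_t
from cmrperf.io import load_table4, table4_summaries, write_results

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df = load_table4()
    report = {"threshold_ml_min_ml": 2.5, "n_vessels": len(df)}
    for model in ("dp", "fermi"):
        summaries = table4_summaries(model)
        counts = detection_counts(summaries)
        normal = [s.mean_mbf_stress for s in summaries if s.group == 1]
        stenotic = [s.mean_mbf_stress for s in summaries if s.group in (2, 3)]
        w = welch_t(normal, stenotic)
        f = f_variance(normal, stenotic)
        report[model] = {
            "counts": counts,
            "mean_mbf_normal": float(np.mean(normal)),
            "mean_mbf_stenotic": float(np.mean(stenotic)),
            "welch_t_normal_vs_stenotic": w.statistic,
            "welch_p": w.p_value,
            "variance_ratio_F": f.statistic,
            "variance_ratio_p": f.p_value,
        }
        print(f"{model}: flagged {counts['flagged_stenotic']}/{counts['n_stenotic']} "
              f"stenotic vessels (group 3: {counts['flagged_group3']}/{counts['n_group3']}, "
              f"group 2: {counts['flagged_group2']}/{counts['n_group2']}); "
              f"normal {report[model]['mean_mbf_normal']:.2f} vs stenotic "
              f"{report[model]['mean_mbf_stenotic']:.2f} mL/min/mL, "
              f"Welch p = {w.p_value:.2g}")
    write_results(RESULTS / "patient_classification.json", report)


if __name__ == "__main__":
    main()
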