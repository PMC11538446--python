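"""Validate the capnodynamic estimator against simulator ground truth.

Runs noise-free single-animal experiments at several true effective
pulmonary blood flows, feeds the synthesized breaths to the estimator, and
tabulates how well EPBF and SvO2 are recovered at steady state. Writes
results/estimator_recovery.csv.

Usage: python analysis/02_estimate_svo2.py
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

import capnosvo as c

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for true_epbf in (2.0, 3.0, 3.5, 4.0, 5.0, 6.0):
        p = replace(c.ScenarioParams(), cardiac_output_lpm=true_epbf / 0.9,
                    shunt_fraction=0.1)
        truth = c.run_scenario([], p, duration_s=2500.0)
        breaths = c.synthesize_breaths(truth, p)
        est = c.process_breaths(breaths, p.hb_gl)
        settled = est[est.t_s > 1500]
        rows.append(
            {
                "true_epbf_lpm": true_epbf,
                "est_epbf_lpm": settled.epbf_lpm.mean(),
                "epbf_error_pct": abs(settled.epbf_lpm.mean() - true_epbf) / true_epbf * 100,
                "true_svo2_pct": truth.svo2_true_pct.iloc[-1],
                "est_svo2_pct": settled.svo2_filt_pct.mean(),
                "svo2_error_points": abs(
                    settled.svo2_filt_pct.mean() - truth.svo2_true_pct.iloc[-1]
                ),
            }
        )
    table = pd.DataFrame(rows).round(4)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "estimator_recovery.csv", index=False)
    print(table.to_string(index=False))
    print(
        f"\nmax EPBF error {table.epbf_error_pct.max():.3f}% | "
        f"max SvO2 error {table.svo2_error_points.max():.2f} points "
        f"-> {out / 'estimator_recovery.csv'}"
    )


if __name__ == "__main__":
    main()
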