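"""Method-comparison analysis of the simulated cohort.

Loads (or regenerates) the cohort recordings and runs the full statistical
battery: per-method inherent precision, the reference method's least
significant change and the derived exclusion zone, repeated-measures
Bland-Altman agreement, and four-quadrant concordance. Writes the report
and the tidy tables behind the Bland-Altman and four-quadrant plots to
results/.

Usage: python analysis/03_method_comparison.py [--seed 42]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import capnosvo as c

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    rec_path = ROOT / "scratch" / f"cohort_seed{args.seed}" / "recordings.csv"
    if rec_path.exists():
        recordings = pd.read_csv(rec_path)
    else:
        print("no cached cohort found; simulating (10 animals)...")
        recordings = c.simulate_cohort(n_animals=10, seed=args.seed)["recordings"]

    report = c.compare_recordings(recordings)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "comparison_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    report.ba_pairs.to_csv(out / "bland_altman_pairs.csv", index=False)
    report.delta_pairs.to_csv(out / "four_quadrant_pairs.csv", index=False)

    print(f"precision (2xCV): "
          + ", ".join(f"{m} {v:.1f}%" for m, v in sorted(report.precision.items())))
    print(f"reference LSC {report.lsc_pct:.1f}% (rounded {report.lsc_pct_rounded}%), "
          f"exclusion zone {report.exclusion_zone:.0f} points")
    for m, r in report.bland_altman.items():
        print(f"{m}: bias {r.bias:+.1f} points, LoA {r.loa_low:+.1f} to "
              f"{r.loa_high:+.1f} ({r.n_pairs} pairs, {r.n_animals} animals)")
    for m, r in report.concordance.items():
        print(f"{m}: concordance {r.rate:.0f}% ({r.n_concordant}/{r.n_outside} "
              f"outside the zone)")
    print(f"report -> {out / 'comparison_report.json'}")


if __name__ == "__main__":
    main()
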