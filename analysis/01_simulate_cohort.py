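"""Simulate the virtual endotoxemia cohort.

Runs the full protocol (LPS induction + seven stabilization-phase
challenges) for 10 virtual pigs under the default measurement model, writes
the large per-second/per-breath tables to scratch/ and a compact per-phase
summary to results/.

Usage: python analysis/01_simulate_cohort.py [--seed 42] [--animals 10]
"""

import argparse
from pathlib import Path

import capnosvo as c

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--animals", type=int, default=10)
    args = ap.parse_args()

    outdir = ROOT / "scratch" / f"cohort_seed{args.seed}"
    outdir.mkdir(parents=True, exist_ok=True)
    tables = c.simulate_cohort(n_animals=args.animals, seed=args.seed)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)

    truth = tables["truth"]
    baseline = truth[truth.t_s < 3000].groupby("animal_id").svo2_true_pct.mean()
    nadir = truth[(truth.t_s > 5000) & (truth.t_s < 7000)].groupby(
        "animal_id"
    ).svo2_true_pct.min()
    summary = (
        tables["recordings"]
        .groupby(["phase", "method"])
        .svo2_pct.agg(["mean", "std"])
        .round(2)
        .reset_index()
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "cohort_phase_summary.csv", index=False)

    print(f"wrote {len(tables['breaths'])} breaths for {args.animals} animals -> {outdir}")
    print(f"baseline true SvO2: {baseline.mean():.1f}% (range {baseline.min():.1f}-{baseline.max():.1f})")
    print(f"sepsis nadir true SvO2: {nadir.mean():.1f}% (range {nadir.min():.1f}-{nadir.max():.1f})")
    print(f"per-phase recording summary -> {results / 'cohort_phase_summary.csv'}")


if __name__ == "__main__":
    main()
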