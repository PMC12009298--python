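#!/usr/bin/env python
"""Score introspective accuracy: self-reports vs fitted choice processes.

Joins the fits from results/fits/ with the cohort's self-reports, computes the
five per-participant accuracy measures (weight correlation, absolute weight
error, heuristic error, reported-model Bayes factor, correct-method flag) and
their permutation-bootstrap chance levels, and writes metrics.csv plus a JSON
summary to results/.

On the default noiseless simulated cohort, reports are perfect by
construction, so accuracy should sit near ceiling and far above chance — the
interesting use is re-running 01 with --noise > 0 to see each metric degrade.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from heurfit import io as hio
from heurfit.metrics import chance_levels, compute_metrics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-boot", type=int, default=1000)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--fits", type=Path, default=ROOT / "results" / "fits")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    reports = {r.participant_id: r for r in hio.read_reports(args.cohort / "reports.csv")}
    fits, rows, paired = [], [], []
    for f in sorted(args.fits.glob("fit_*.json")):
        pf = hio.read_participant_fit(f)
        rep = reports[pf.participant_id]
        fits.append(pf)
        paired.append(rep)
        rows.append(dataclasses.asdict(compute_metrics(pf, rep)))
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "metrics.csv", index=False)

    corr = table["weight_correlation"].dropna()
    chance = chance_levels(fits, paired, n_boot=args.n_boot, seed=args.seed)
    summary = {
        "n_participants": len(table),
        "mean_weight_correlation": float(corr.mean()),
        "n_undefined_correlations": int(table["weight_correlation"].isna().sum()),
        "mean_absolute_weight_error": float(table["absolute_weight_error"].mean()),
        "mean_heuristic_error": float(table["heuristic_error"].mean()),
        "mean_reported_model_bayes_factor": float(
            table["reported_model_bayes_factor"].mean()),
        "fraction_correct_method": float(table["correct_method"].mean()),
        "chance_levels": dataclasses.asdict(chance),
    }
    (args.out / "accuracy_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"Scored {len(table)} participants -> {args.out / 'metrics.csv'}")
    print(f"mean weight correlation:        {summary['mean_weight_correlation']:.3f} "
          f"(chance {chance.weight_correlation:.3f})")
    print(f"mean heuristic error:           {summary['mean_heuristic_error']:.3f} "
          f"(chance {chance.heuristic_error:.3f})")
    print(f"mean reported-model Bayes factor {summary['mean_reported_model_bayes_factor']:.3f} "
          f"(chance {chance.reported_model_bayes_factor:.3f})")
    print(f"fraction correct method:        {summary['fraction_correct_method']:.3f} "
          f"(chance {chance.correct_method:.3f}; analytic 1/6 = 0.167)")


if __name__ == "__main__":
    main()
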