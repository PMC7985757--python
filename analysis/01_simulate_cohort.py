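"""Generate the synthetic metastatic-breast-cancer cohort.

Draws a scaled-down (default 500-patient) cohort from the study-like
defaults — six latent trajectory groups (three changing, three flat) on
the transformed TSDS scale, time-varying treatment/care flags, per-group
death hazards, administrative censoring — then injects the raw-data
pathologies the preprocessing rules target (same-day duplicates, missing
items, <3-assessment patients, all-zero patients).  Writes the three raw
tables under results/cohort/.
"""

import argparse
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from symtraj import (  # noqa: E402
    ESAS_ITEMS,
    SimulationConfig,
    generate_cohort,
    inject_artifacts,
    write_cohort,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-patients", type=int, default=500)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path(__file__).resolve().parents[1]
                    / "results" / "cohort")
    args = ap.parse_args()

    cfg = SimulationConfig(n_patients=args.n_patients, seed=args.seed)
    assessments, patients, truth = generate_cohort(cfg)
    assessments = inject_artifacts(assessments, cfg)
    write_cohort(args.out, assessments, patients, truth)
    cfg.to_yaml(args.out / "config.yaml")

    per_patient = assessments.groupby("patient_id").size()
    items = assessments[list(ESAS_ITEMS)]
    print(f"cohort: {len(patients)} patients, {len(assessments)} raw assessments "
          f"({per_patient.mean():.1f}/patient)")
    print(f"  deaths within follow-up: {truth['death_month'].notna().sum()}")
    print(f"  duplicate rows injected: "
          f"{assessments['artifact'].str.contains('duplicate').sum()}")
    print(f"  missing item cells: {int(items.isna().to_numpy().sum())}")
    print(f"  tables written to {args.out}")


if __name__ == "__main__":
    main()
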