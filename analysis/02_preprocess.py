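"""Apply the cohort-construction rules and build the modeling dataset.

Computes the TSDS per assessment (imputing when <=50% of items are
missing, excluding otherwise), keeps the higher-scoring same-day
duplicate, removes patients with <3 assessments / all-zero scores /
missing income quintile, caps each patient at the first 30 assessments,
and Box-Cox transforms the outcome.  Writes the modeling dataset and
the exclusion log under results/dataset/.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from symtraj import preprocess_cohort, read_cohort  # noqa: E402


def main():
    root = pathlib.Path(__file__).resolve().parents[1]
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=pathlib.Path, default=root / "results" / "cohort")
    ap.add_argument("--out", type=pathlib.Path, default=root / "results" / "dataset")
    args = ap.parse_args()

    assessments, patients, _ = read_cohort(args.cohort)
    ds, log = preprocess_cohort(assessments, patients)
    args.out.mkdir(parents=True, exist_ok=True)
    ds.obs.to_csv(args.out / "dataset.csv", index=False)
    ds.patients.to_csv(args.out / "baseline.csv")
    log.to_csv(args.out / "exclusions.csv", index=False)

    print(f"retained: {ds.n_patients} patients, {len(ds.obs)} assessments")
    print("exclusions by reason:")
    print(log.groupby("reason")["n"].sum().to_string())
    print(f"dataset written to {args.out}")


if __name__ == "__main__":
    main()
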