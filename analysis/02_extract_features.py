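#!/usr/bin/env python
"""Preprocess every subject and extract the 11 band-power features.

Each trial is band-pass filtered (5th-order Butterworth, 0.5-100 Hz,
zero-phase), resampled to the 200 Hz effective rate, decomposed with a
5-level db4 DWT, and summarized as 11 features: average Welch power in
alpha/beta/gamma/theta, the three alpha-relative power ratios, and the
in-band PSD variance ("varied power") per band.

Per-subject feature matrices go to scratch/features/ (reused by later
stages); a per-class feature summary for subject S00 goes to
results/feature_class_means.csv.
"""

from pathlib import Path

import pandas as pd

from mipower import FeatureMatrix, SyntheticConfig, extract_matrix, generate_trialset
from mipower.report import preprocess_trialset

ROOT = Path(__file__).resolve().parents[1]
SEEDS = range(10)


def feature_path(seed: int) -> Path:
    return ROOT / "scratch" / "features" / f"subject{seed:02d}.csv"


def load_or_extract(seed: int) -> FeatureMatrix:
    path = feature_path(seed)
    if path.exists():
        return FeatureMatrix.from_csv(path)
    trials = generate_trialset(SyntheticConfig(seed=seed))
    fm = extract_matrix(preprocess_trialset(trials))
    path.parent.mkdir(parents=True, exist_ok=True)
    fm.to_csv(path)
    return fm


def main() -> None:
    for seed in SEEDS:
        fm = load_or_extract(seed)
        print(f"S{seed:02d}: {fm.features.shape[0]} trials x {fm.features.shape[1]} features")

    fm0 = load_or_extract(0)
    means = fm0.features.groupby(fm0.labels).mean().T
    means["feet_over_hand"] = means["feet"] / means["hand"]
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    means.to_csv(results / "feature_class_means.csv")
    print("\nSubject S00 class means (feet/hand ratio shows the ERD/ERS contrast):")
    print(means.round(4).to_string())
    print(
        "\nAlpha-driven features rise for feet trials and beta-driven ones "
        "fall, though the 1/f background dilutes the raw amplitude contrast "
        "(x1.4 / x0.7) in the measured band powers; the alpha-relative "
        "ratios combine both shifts and separate the classes strongly."
    )


if __name__ == "__main__":
    main()
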