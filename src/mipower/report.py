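"""Pipeline orchestration and feature-ablation reporting.

Runs the full chain — simulate (or read) trials, band-pass filter,
resample to the 200 Hz effective rate, extract the 11 band-power
features, rank them with all three methods, benchmark the five
classifiers — and then measures what each feature subset costs in
accuracy: all features, all minus the relative-power ratios, and the
subset each ranking method selects.  "Loss in accuracy" is the
all-features accuracy minus the subset accuracy, in percentage points;
a negative loss means the subset actually did better.

Per-"subject" rows are realized as independent synthetic sessions
differing by seed.  The ablation classifier defaults to weighted KNN,
the strongest of the five on this feature set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, ranking, subbands
from .classify import ClassifierSpec, CVReport
from .preprocess import EFFECTIVE_FS, FilterSpec, apply_filter, read_trialset, resample_to_effective
from .ranking import RankingResult
from .subbands import FEATURE_NAMES, RELATIVE_FEATURE_INDICES, FeatureMatrix
from .synthetic import SyntheticConfig, TrialSet, generate_trialset

__all__ = [
    "ABLATION_COLUMNS",
    "AblationRow",
    "PipelineResult",
    "subset_accuracy",
    "loss_in_accuracy",
    "preprocess_trialset",
    "run_pipeline",
    "run_study",
]

ABLATION_COLUMNS = (
    "accuracy_all",
    "accuracy_without_relative",
    "accuracy_mi_subset",
    "accuracy_chi2_subset",
    "accuracy_corr_survivors",
)

ALL_FEATURES = tuple(range(1, len(FEATURE_NAMES) + 1))


def subset_accuracy(
    features: FeatureMatrix,
    labels=None,
    subset=ALL_FEATURES,
    spec: ClassifierSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean CV accuracy (%) using only the given canonical feature indices."""
    subset = list(subset)
    if not subset:
        raise ValueError("feature subset must be nonempty")
    if any(i < 1 or i > len(FEATURE_NAMES) for i in subset):
        raise ValueError(f"subset indices must lie in 1..{len(FEATURE_NAMES)}")
    y = np.asarray(labels if labels is not None else features.labels)
    X = features.values[:, [i - 1 for i in subset]]
    report = classify.stratified_kfold_eval(X, y, spec, n_folds=n_folds, seed=seed)
    return report.mean_accuracy


def loss_in_accuracy(accuracy_all: float, accuracy_subset: float) -> float:
    """Percentage-point drop from the all-features accuracy (may be negative)."""
    for a in (accuracy_all, accuracy_subset):
        if not 0 <= a <= 100:
            raise ValueError("accuracies must lie in [0, 100]")
    return accuracy_all - accuracy_subset


@dataclass
class AblationRow:
    """One subject's ablation accuracies, subsets and losses."""

    subject: str
    accuracies: dict          # column -> accuracy %
    subsets: dict             # column -> 1-based feature indices used
    losses: dict              # column -> accuracy_all - accuracy_subset
    classifier: str
    n_folds: int
    seed: int


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    subject: str
    feature_matrix: FeatureMatrix
    rankings: dict[str, RankingResult]
    cv_reports: list[CVReport]
    ablation: AblationRow
    manifest: dict = field(default_factory=dict)


def preprocess_trialset(
    trials: TrialSet,
    filter_spec: FilterSpec | None = None,
    effective_fs: float = EFFECTIVE_FS,
) -> TrialSet:
    """Band-pass at the native rate, then resample to the effective rate."""
    if filter_spec is None:
        filter_spec = FilterSpec(fs=trials.fs)
    filtered = apply_filter(trials, filter_spec)
    return resample_to_effective(filtered, effective_fs)


def _ablation_row(
    fm: FeatureMatrix,
    rankings: dict[str, RankingResult],
    subject: str,
    spec: ClassifierSpec,
    n_folds: int,
    seed: int,
) -> AblationRow:
    without_relative = [
        i for i in ALL_FEATURES if i not in RELATIVE_FEATURE_INDICES
    ]
    subsets = {
        "accuracy_all": list(ALL_FEATURES),
        "accuracy_without_relative": without_relative,
        "accuracy_mi_subset": rankings["mutual_information"].selected,
        "accuracy_chi2_subset": rankings["chi_square"].selected,
        "accuracy_corr_survivors": rankings["correlation"].selected,
    }
    accuracies = {
        col: subset_accuracy(fm, subset=idx, spec=spec, n_folds=n_folds, seed=seed)
        for col, idx in subsets.items()
    }
    losses = {
        col: loss_in_accuracy(accuracies["accuracy_all"], accuracies[col])
        for col in ABLATION_COLUMNS
        if col != "accuracy_all"
    }
    return AblationRow(
        subject=subject,
        accuracies=accuracies,
        subsets=subsets,
        losses=losses,
        classifier=spec.name,
        n_folds=n_folds,
        seed=seed,
    )


def run_pipeline(
    config: SyntheticConfig | str | Path,
    outdir: str | Path | None = None,
    ablation_classifier: str = "weighted_knn",
    n_folds: int = 5,
    n_iterations: int = 10,
    filter_spec: FilterSpec | None = None,
    effective_fs: float = EFFECTIVE_FS,
) -> PipelineResult:
    """Full analysis for one subject (synthetic config or serialized path).

    Stage failures abort with the stage name attached.  When ``outdir``
    is given, features, rankings, classifier reports, the ablation row
    and a machine-readable manifest are written there.
    """
    stage = "input"
    try:
        if isinstance(config, SyntheticConfig):
            trials = generate_trialset(config)
            seed = config.seed
            config_dict = config.to_dict()
        else:
            trials = read_trialset(config)
            seed = 0
            config_dict = {"input_path": str(config)}
        subject = trials.subject_id or "subject"

        stage = "preprocess"
        prepared = preprocess_trialset(trials, filter_spec, effective_fs)

        stage = "feature extraction"
        fm = subbands.extract_matrix(prepared)

        stage = "feature ranking"
        rankings = {
            method: ranking.rank_features(
                fm, method=method, n_iterations=n_iterations, seed=seed
            )
            for method in ranking.METHODS
        }

        stage = "classification"
        cv_reports = classify.benchmark_all(fm, n_folds=n_folds, seed=seed)

        stage = "ablation"
        spec = ClassifierSpec(ablation_classifier, seed=seed)
        ablation = _ablation_row(fm, rankings, subject, spec, n_folds, seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "subject": subject,
        "config": config_dict,
        "seed": seed,
        "n_folds": n_folds,
        "n_iterations": n_iterations,
        "effective_fs": effective_fs,
        "feature_names": list(FEATURE_NAMES),
        "ablation_classifier": ablation_classifier,
        "selected_subsets": {m: r.selected for m, r in rankings.items()},
    }
    result = PipelineResult(
        subject=subject,
        feature_matrix=fm,
        rankings=rankings,
        cv_reports=cv_reports,
        ablation=ablation,
        manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.feature_matrix.to_csv(outdir / "features.csv")
    for method, rr in result.rankings.items():
        payload = {
            "method": rr.method,
            "selected": rr.selected,
            "selection_rule": rr.selection_rule,
            "n_iterations": rr.n_iterations,
            "seed": rr.seed,
            "per_iteration_ranks": rr.per_iteration_ranks.to_dict(orient="list"),
            "per_iteration_scores": rr.per_iteration_scores.to_dict(orient="list"),
        }
        (outdir / f"ranking_{method}.json").write_text(json.dumps(payload, indent=1))
    classifier_table(
        {result.subject: result.cv_reports}
    ).to_csv(outdir / "classifier_report.csv")
    ablation_table([result.ablation]).to_csv(outdir / "ablation.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))


def classifier_table(reports_by_subject: dict[str, list[CVReport]]) -> pd.DataFrame:
    """Accuracy table: subjects as rows, classifiers as columns."""
    rows = {}
    for subject, reports in reports_by_subject.items():
        rows[subject] = {r.classifier: r.mean_accuracy for r in reports}
    table = pd.DataFrame(rows).T
    table.index.name = "subject"
    if len(table) > 1:
        table.loc["AVG"] = table.mean()
    return table


def ablation_table(rows: list[AblationRow]) -> pd.DataFrame:
    """Ablation accuracies per subject (5 accuracy columns + losses)."""
    records = []
    for row in rows:
        rec = {"subject": row.subject}
        rec.update({col: row.accuracies[col] for col in ABLATION_COLUMNS})
        rec.update({f"loss_{col}": v for col, v in row.losses.items()})
        records.append(rec)
    return pd.DataFrame(records)


def run_study(
    configs: list[SyntheticConfig],
    ablation_classifier: str = "weighted_knn",
    n_folds: int = 5,
    n_iterations: int = 10,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PipelineResult]]:
    """Run the pipeline for several synthetic subjects.

    Returns the subjects x classifiers accuracy table, the ablation
    table, and the per-subject results.
    """
    results = [
        run_pipeline(
            cfg,
            ablation_classifier=ablation_classifier,
            n_folds=n_folds,
            n_iterations=n_iterations,
        )
        for cfg in configs
    ]
    acc_table = classifier_table(
        {res.subject: res.cv_reports for res in results}
    )
    abl_table = ablation_table([res.ablation for res in results])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        acc_table.to_csv(outdir / "classifier_report.csv")
        abl_table.to_csv(outdir / "ablation.csv", index=False)
    return acc_table, abl_table, results
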