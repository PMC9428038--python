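"""Pixel-based and patient-based evaluation of the fitted models.

Two regimes: per-spectrum confusion-matrix statistics (sensitivity,
specificity, PPV, NPV, one-vs-rest per subtype), and the patient-level
majority vote — each patient is called correctly classified at cut-off c
iff the fraction of their evaluated spectra predicted as the true subtype
is >= c, swept over cut-offs 50-95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, preprocess
from .phantom import SUBTYPES, PhantomConfig, generate_cohort

DEFAULT_CUTOFFS = (0.50, 0.60, 0.70, 0.80, 0.90, 0.95)


# ---------------------------------------------------------------------------
# Pixel-based regime
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true label, columns = predicted label."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion(
    prediction_table: pd.DataFrame, labels: tuple[str, ...] = SUBTYPES
) -> ConfusionMatrix:
    """Accumulate true/predicted counts in the fixed label order
    (SQ, LUAD, SCLC by default)."""
    if len(prediction_table) == 0:
        raise ValueError("prediction table is empty")
    true = prediction_table["subtype"].to_numpy()
    pred = prediction_table["predicted"].to_numpy()
    foreign = (set(true) | set(pred)) - set(labels)
    if foreign:
        raise ValueError(f"labels outside the fixed label set: {sorted(foreign)}")
    idx = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true, pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, PPV and NPV per class.

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """
    if len(cm.labels) < 2:
        raise ValueError("need at least 2 classes")
    C = cm.counts.astype(float)
    total = C.sum()
    rows = {}
    for k, lab in enumerate(cm.labels):
        tp = C[k, k]
        fn = C[k].sum() - tp
        fp = C[:, k].sum() - tp
        tn = total - tp - fn - fp

        def _ratio(num: float, den: float) -> float:
            return num / den if den > 0 else float("nan")

        rows[lab] = {
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "ppv": _ratio(tp, tp + fp),
            "npv": _ratio(tn, tn + fn),
        }
    return pd.DataFrame(rows).T.loc[list(cm.labels)]


# ---------------------------------------------------------------------------
# Patient-based regime
# ---------------------------------------------------------------------------

def patient_fractions(prediction_table: pd.DataFrame) -> pd.DataFrame:
    """Per patient: the fraction of evaluated spectra predicted as the true
    subtype. Columns: patient_id, subtype, n_test, n_correct, fraction."""
    if len(prediction_table) == 0:
        raise ValueError("prediction table is empty")
    records = []
    for pid, grp in prediction_table.groupby("patient_id", sort=False):
        true_labels = grp["subtype"].unique()
        if len(true_labels) != 1:
            raise ValueError(
                f"patient {pid!r} carries inconsistent true labels: "
                f"{sorted(true_labels)}"
            )
        n = len(grp)
        n_correct = int((grp["predicted"] == true_labels[0]).sum())
        records.append(
            {
                "patient_id": pid,
                "subtype": true_labels[0],
                "n_test": n,
                "n_correct": n_correct,
                "fraction": n_correct / n,
            }
        )
    return pd.DataFrame.from_records(records)


def cutoff_sweep(
    vote_results: pd.DataFrame,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    labels: tuple[str, ...] = SUBTYPES,
) -> pd.DataFrame:
    """Patient-level accuracy per subtype across cut-off values.

    A patient counts as correct at cut-off c iff fraction >= c. Columns:
    cutoff, subtype, n_correct, n_total, accuracy.
    """
    if len(vote_results) == 0:
        raise ValueError("vote results are empty")
    for c in cutoffs:
        if not (0 < c <= 1):
            raise ValueError(f"cut-off {c} outside (0, 1]")
    records = []
    for c in sorted(cutoffs):
        for lab in labels:
            grp = vote_results[vote_results["subtype"] == lab]
            n_total = len(grp)
            n_correct = int((grp["fraction"] >= c).sum())
            records.append(
                {
                    "cutoff": c,
                    "subtype": lab,
                    "n_correct": n_correct,
                    "n_total": n_total,
                    "accuracy": n_correct / n_total if n_total else float("nan"),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Everything one pipeline run produces, per model."""

    config: PhantomConfig
    predictions: dict[str, pd.DataFrame]
    confusions: dict[str, ConfusionMatrix]
    metrics: dict[str, pd.DataFrame]
    votes: dict[str, pd.DataFrame]
    sweeps: dict[str, pd.DataFrame]
    denoise_report: preprocess.DenoiseReport | None = None


def run_full_experiment(
    cohort_config: PhantomConfig,
    model_list: list[str | tuple[str, dict]],
    *,
    n_factors: int = 20,
    atmospheric: bool = True,
    fingerprint: tuple[float, float] = (1800.0, 648.0),
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    vote_pool: str = "test",
) -> ExperimentResult:
    """Generate -> preprocess -> split -> fit/predict each model -> evaluate.

    ``model_list`` entries are registry names ("svm-c", "lda-linear", ...)
    optionally paired with a hyperparameter dict, e.g. ("svm-c", {"C": 1.0}).
    ``vote_pool`` selects the spectra entering the patient vote: "test"
    (default — training spectra never score their own fit) or "all".
    """
    if not model_list:
        raise ValueError("model list is empty")
    if vote_pool not in ("test", "all"):
        raise ValueError("vote_pool must be 'test' or 'all'")

    cohort = generate_cohort(cohort_config)
    table = preprocess.flatten_cohort(cohort)
    if atmospheric:
        refs = preprocess.AtmosphericReferenceSet.synthetic(table.grid)
        table, _ = preprocess.atmospheric_correct(table, refs)
    table, report = preprocess.pca_denoise(table, n_factors=n_factors)
    table = preprocess.slice_fingerprint(table, *fingerprint)
    split = classify.split_alternating(table)

    predictions, confusions, metrics, votes, sweeps = {}, {}, {}, {}, {}
    for entry in model_list:
        name, hyper = entry if isinstance(entry, tuple) else (entry, {})
        model = classify.fit_model(split, name, **hyper)
        pred = classify.predict_table(model, split)
        if vote_pool == "all":
            mask = (split.meta["role"] == "train").to_numpy()
            train_pred = split.meta.loc[mask].reset_index(drop=True).copy()
            train_pred["predicted"] = classify.predict_model(
                model, split.spectra[mask]
            )
            train_pred["model"] = model.name
            vote_input = pd.concat([pred, train_pred], ignore_index=True)
        else:
            vote_input = pred
        predictions[name] = pred
        confusions[name] = confusion(pred)
        metrics[name] = class_metrics(confusions[name])
        votes[name] = patient_fractions(vote_input)
        sweeps[name] = cutoff_sweep(votes[name], cutoffs=cutoffs)

    return ExperimentResult(
        config=cohort_config,
        predictions=predictions,
        confusions=confusions,
        metrics=metrics,
        votes=votes,
        sweeps=sweeps,
        denoise_report=report,
    )


def sweep_to_wide(sweeps: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-model sweeps into one wide table: rows (cutoff, subtype),
    one "k/n (pct)" style numeric pair of columns per model."""
    frames = []
    for name, sw in sweeps.items():
        f = sw.set_index(["cutoff", "subtype"])[["n_correct", "n_total", "accuracy"]]
        f.columns = pd.MultiIndex.from_product([[name], f.columns])
        frames.append(f)
    return pd.concat(frames, axis=1).reset_index()
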