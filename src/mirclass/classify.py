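"""Supervised subtype classifiers and the alternating train/test split.

Five models: Bayes discriminants with pooled covariance (linear), per-class
covariance with determinant term (quadratic), per-class Mahalanobis distance
to the centroid (no determinant, no prior), and soft-margin linear support
vector classifiers in the C and nu parameterizations with one-vs-one voting.

Conventions shared by all models: class priors uniform (the cohort design is
balanced), covariance estimators unbiased (n-1 / pooled df), covariances
ridge-augmented by ``ridge_eps * mean(diag) * I``, no feature scaling by
default (an optional per-channel standardization is recorded in the fitted
model), and deterministic tie-breaking toward the lexicographically smaller
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC, NuSVC

from .preprocess import SpectrumTable

DISCRIMINANT_VARIANTS = ("linear", "quadratic", "mahalanobis")
MARGIN_FORMULATIONS = ("c_svc", "nu_svc")


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_alternating(table: SpectrumTable) -> SpectrumTable:
    """Assign roles: within each patient, in flatten (row-major) order,
    even 0-based positions become training spectra, odd ones test spectra.

    Emulates taking "every second" spectrum of each image as the training
    half; per-patient scope keeps both halves balanced for the patient vote.
    """
    out = table.copy()
    if out.n_spectra == 0:
        return out
    pos = out.meta.groupby("patient_id", sort=False).cumcount()
    out.meta["role"] = np.where(pos % 2 == 0, "train", "test")
    return out


def _training_arrays(split: SpectrumTable) -> tuple[np.ndarray, np.ndarray]:
    mask = (split.meta["role"] == "train").to_numpy()
    if not mask.any():
        raise ValueError("no training rows in split table")
    return split.spectra[mask], split.meta.loc[mask, "subtype"].to_numpy()


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant channels pass through unscaled
    return mean, sd


def _apply_scaler(X: np.ndarray, mean, sd) -> np.ndarray:
    if mean is None:
        return X
    return (X - mean) / sd


# ---------------------------------------------------------------------------
# Discriminant models
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Fitted Gaussian discriminant state.

    ``covariances`` holds one pooled matrix (linear variant) broadcast per
    class, or per-class matrices (quadratic / mahalanobis), all already
    ridge-augmented.
    """

    variant: str
    labels: list[str]            # lexicographic order; drives tie-breaking
    means: np.ndarray            # (K, p)
    covariances: np.ndarray      # (K, p, p)
    priors: np.ndarray           # (K,)
    ridge_eps: float
    grid_channels: np.ndarray    # wavenumbers the model was fitted on
    scaler_mean: np.ndarray | None = None   # per-channel standardization,
    scaler_sd: np.ndarray | None = None     # None when disabled

    def __post_init__(self) -> None:
        if self.variant not in DISCRIMINANT_VARIANTS:
            raise ValueError(f"unknown discriminant variant {self.variant!r}")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    @property
    def name(self) -> str:
        return f"lda-{self.variant}"


def _ridge_augment(cov: np.ndarray, ridge_eps: float) -> np.ndarray:
    p = cov.shape[0]
    return cov + ridge_eps * float(np.mean(np.diag(cov))) * np.eye(p)


def _assert_pd(cov: np.ndarray, context: str) -> None:
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"{context} covariance is singular; increase ridge_eps"
        ) from None


def fit_discriminant(
    split: SpectrumTable, variant: str, ridge_eps: float = 1e-6,
    standardize: bool = False,
) -> DiscriminantModel:
    """Fit class means and (pooled or per-class) covariances on the training
    rows. ``standardize=True`` z-scores each channel on the training set
    first (off by default; the scaler is recorded in the model)."""
    if variant not in DISCRIMINANT_VARIANTS:
        raise ValueError(f"unknown discriminant variant {variant!r}")
    X, y = _training_arrays(split)
    scaler_mean = scaler_sd = None
    if standardize:
        scaler_mean, scaler_sd = _fit_scaler(X)
        X = _apply_scaler(X, scaler_mean, scaler_sd)
    labels = sorted(set(split.meta["subtype"]))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes to fit a discriminant")
    for lab in labels:
        n = int(np.sum(y == lab))
        if n == 0:
            raise ValueError(f"class {lab!r} absent from the training rows")
        if n < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 training rows")

    p = X.shape[1]
    K = len(labels)
    means = np.empty((K, p))
    per_class_cov = np.empty((K, p, p))
    ns = np.empty(K, dtype=int)
    for k, lab in enumerate(labels):
        Xk = X[y == lab]
        ns[k] = len(Xk)
        means[k] = Xk.mean(axis=0)
        per_class_cov[k] = np.cov(Xk, rowvar=False, ddof=1).reshape(p, p)

    if variant == "linear":
        pooled = np.tensordot(ns - 1, per_class_cov, axes=1) / (ns.sum() - K)
        pooled = _ridge_augment(pooled, ridge_eps)
        _assert_pd(pooled, "pooled")
        covs = np.repeat(pooled[None], K, axis=0)
    else:
        covs = np.empty_like(per_class_cov)
        for k, lab in enumerate(labels):
            covs[k] = _ridge_augment(per_class_cov[k], ridge_eps)
            _assert_pd(covs[k], f"class {lab!r}")

    return DiscriminantModel(
        variant=variant,
        labels=labels,
        means=means,
        covariances=covs,
        priors=np.full(K, 1.0 / K),
        ridge_eps=ridge_eps,
        grid_channels=split.grid.values,
        scaler_mean=scaler_mean,
        scaler_sd=scaler_sd,
    )


def discriminant_scores(model: DiscriminantModel, spectra: np.ndarray) -> np.ndarray:
    """Per-class decision scores (higher = preferred), shape (n, K).

    linear:      x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + ln pi_k
    quadratic:   -ln|S_k|/2 - (x-mu_k)' S_k^-1 (x-mu_k)/2 + ln pi_k
    mahalanobis: -(x-mu_k)' S_k^-1 (x-mu_k)   (distance only, negated)
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"query has {X.shape[1]} channels, model expects {model.means.shape[1]}"
        )
    X = _apply_scaler(X, model.scaler_mean, model.scaler_sd)
    K = len(model.labels)
    scores = np.empty((X.shape[0], K))
    for k in range(K):
        cov = model.covariances[k]
        L = np.linalg.cholesky(cov)
        mu = model.means[k]
        if model.variant == "linear":
            a = np.linalg.solve(cov, mu)  # S^-1 mu
            scores[:, k] = X @ a - 0.5 * mu @ a + np.log(model.priors[k])
        else:
            diff = X - mu
            z = np.linalg.solve(L, diff.T)  # L z = diff'
            maha = np.sum(z**2, axis=0)
            if model.variant == "quadratic":
                logdet = 2.0 * np.sum(np.log(np.diag(L)))
                scores[:, k] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[k])
            else:
                scores[:, k] = -maha
    return scores


def predict_discriminant(model: DiscriminantModel, spectra: np.ndarray) -> np.ndarray:
    """Labels maximizing the variant's score; exact ties resolve to the
    lexicographically smaller label (labels are stored sorted, argmax takes
    the first maximum)."""
    scores = discriminant_scores(model, spectra)
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.labels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Margin (SVM) models
# ---------------------------------------------------------------------------

@dataclass
class BinaryMachine:
    """One one-vs-one linear machine.

    Decision d(x) = x . w + b; d > 0 votes for ``label_pos`` (the
    lexicographically larger of the pair), d <= 0 for ``label_neg``.
    """

    label_neg: str
    label_pos: str
    w: np.ndarray
    b: float
    support_indices: np.ndarray   # positions in the full training table
    dual_coef: np.ndarray         # y_i alpha_i per support vector

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


@dataclass
class MarginModel:
    """One-vs-one linear soft-margin classifier (C-SVC or nu-SVC)."""

    formulation: str
    labels: list[str]
    machines: list[BinaryMachine]
    hyperparameter: float         # C or nu
    grid_channels: np.ndarray
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.formulation not in MARGIN_FORMULATIONS:
            raise ValueError(f"unknown SVM formulation {self.formulation!r}")

    @property
    def name(self) -> str:
        return "svm-c" if self.formulation == "c_svc" else "svm-nu"


def nu_feasibility_bound(n_a: int, n_b: int) -> float:
    """Largest feasible nu for a binary problem with class sizes n_a, n_b."""
    return 2.0 * min(n_a, n_b) / (n_a + n_b)


def fit_margin(
    split: SpectrumTable, formulation: str, C_or_nu: float | None = None,
    standardize: bool = False,
) -> MarginModel:
    """Fit K(K-1)/2 one-vs-one linear machines on the training rows.

    Defaults: C = 1 for c_svc, nu = 0.5 for nu_svc. Deterministic for fixed
    input (the underlying dual solver has no randomized initialization for
    fixed data ordering). An infeasible nu is rejected up front, citing the
    2*min(n_a,n_b)/(n_a+n_b) bound of the violating pair.
    """
    if formulation not in MARGIN_FORMULATIONS:
        raise ValueError(f"unknown SVM formulation {formulation!r}")
    if C_or_nu is None:
        C_or_nu = 1.0 if formulation == "c_svc" else 0.5
    if formulation == "c_svc" and C_or_nu <= 0:
        raise ValueError(f"C must be positive, got {C_or_nu}")
    if formulation == "nu_svc" and not (0 < C_or_nu < 1):
        raise ValueError(f"nu must lie in (0, 1), got {C_or_nu}")

    X, y = _training_arrays(split)
    scaler_mean = scaler_sd = None
    if standardize:
        scaler_mean, scaler_sd = _fit_scaler(X)
        X = _apply_scaler(X, scaler_mean, scaler_sd)
    labels = sorted(set(split.meta["subtype"]))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes to fit an SVM")
    for lab in labels:
        if not np.any(y == lab):
            raise ValueError(f"class {lab!r} absent from the training rows")

    train_positions = np.flatnonzero((split.meta["role"] == "train").to_numpy())
    machines = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            pair_mask = (y == a) | (y == b)
            Xp, yp = X[pair_mask], y[pair_mask]
            n_a, n_b = int(np.sum(yp == a)), int(np.sum(yp == b))
            if formulation == "nu_svc":
                bound = nu_feasibility_bound(n_a, n_b)
                if C_or_nu > bound:
                    raise ValueError(
                        f"nu = {C_or_nu} infeasible for pair ({a}, {b}): "
                        f"nu <= 2*min(n_a, n_b)/(n_a + n_b) = {bound:.6g} required"
                    )
                clf = NuSVC(nu=C_or_nu, kernel="linear", tol=1e-6)
            else:
                clf = SVC(C=C_or_nu, kernel="linear", tol=1e-6)
            clf.fit(Xp, yp)
            # sklearn sorts classes lexicographically: classes_[1] == b gets d > 0
            assert list(clf.classes_) == [a, b]
            pair_positions = train_positions[pair_mask]
            machines.append(
                BinaryMachine(
                    label_neg=a,
                    label_pos=b,
                    w=clf.coef_[0].copy(),
                    b=float(clf.intercept_[0]),
                    support_indices=pair_positions[clf.support_],
                    dual_coef=clf.dual_coef_[0].copy(),
                )
            )
    return MarginModel(
        formulation=formulation,
        labels=labels,
        machines=machines,
        hyperparameter=float(C_or_nu),
        grid_channels=split.grid.values,
        scaler_mean=scaler_mean,
        scaler_sd=scaler_sd,
    )


def predict_margin(model: MarginModel, spectra: np.ndarray) -> np.ndarray:
    """One-vs-one voting. Vote ties break toward the larger sum of signed
    decision values over the tied labels' machines, then lexicographically."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    p = len(model.grid_channels)
    if X.shape[1] != p:
        raise ValueError(f"query has {X.shape[1]} channels, model expects {p}")
    X = _apply_scaler(X, model.scaler_mean, model.scaler_sd)
    labels = model.labels
    lab_idx = {lab: k for k, lab in enumerate(labels)}
    n, K = X.shape[0], len(labels)
    votes = np.zeros((n, K), dtype=int)
    signed = np.zeros((n, K))
    for m in model.machines:
        d = m.decision(X)
        pos = d > 0
        votes[pos, lab_idx[m.label_pos]] += 1
        votes[~pos, lab_idx[m.label_neg]] += 1
        signed[:, lab_idx[m.label_pos]] += d
        signed[:, lab_idx[m.label_neg]] -= d
    out = np.empty(n, dtype=object)
    for r in range(n):
        best = votes[r].max()
        tied = np.flatnonzero(votes[r] == best)
        if len(tied) > 1:
            strongest = signed[r, tied].max()
            tied = tied[signed[r, tied] == strongest]
        out[r] = labels[tied[0]]  # labels sorted -> lexicographic fallback
    return out


# ---------------------------------------------------------------------------
# Uniform front-end
# ---------------------------------------------------------------------------

MODEL_NAMES = ("lda-linear", "lda-quadratic", "lda-mahalanobis", "svm-c", "svm-nu")


def fit_model(split: SpectrumTable, name: str, **hyper):
    """Fit any of the five models by its registry name."""
    standardize = hyper.pop("standardize", False)
    if name.startswith("lda-"):
        return fit_discriminant(split, name[4:], standardize=standardize, **hyper)
    if name == "svm-c":
        return fit_margin(split, "c_svc", hyper.get("C"), standardize=standardize)
    if name == "svm-nu":
        return fit_margin(split, "nu_svc", hyper.get("nu"), standardize=standardize)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def predict_model(model, spectra: np.ndarray) -> np.ndarray:
    if isinstance(model, DiscriminantModel):
        return predict_discriminant(model, spectra)
    if isinstance(model, MarginModel):
        return predict_margin(model, spectra)
    raise TypeError(f"not a fitted mirclass model: {type(model)!r}")


def predict_table(model, split: SpectrumTable) -> pd.DataFrame:
    """Predict the test rows of a split table.

    Returns the test rows' metadata plus ``predicted`` and ``model`` columns
    (one prediction per test row).
    """
    mask = (split.meta["role"] == "test").to_numpy()
    if not mask.any():
        raise ValueError("no test rows in split table")
    preds = predict_model(model, split.spectra[mask])
    out = split.meta.loc[mask].reset_index(drop=True).copy()
    out["predicted"] = preds
    out["model"] = model.name
    return out
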