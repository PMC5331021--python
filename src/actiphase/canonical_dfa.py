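"""Canonical discriminant-function analysis for phase classification.

Implements the full classical machinery: standardized residual scores as
predictors, a MANOVA screen (Wilks' Λ with Rao's F approximation),
canonical discriminant functions from the eigendecomposition of
W⁻¹B (within- vs between-group scatter), Bartlett's χ² sequential test,
the structure matrix of pooled within-group predictor–score correlations,
Fisher linear classification functions, apparent and leave-one-out
classification tables with a Pearson χ² of the confusion matrix, and a
stratified case bootstrap.

Conventions follow the classical SPSS presentation: discriminant scores
are scaled to pooled within-group variance 1 and centred at the grand
mean (so the group-size-weighted centroid mean is exactly 0), canonical
correlation_i = sqrt(λ_i/(1+λ_i)), Wilks Λ_k = Π_{i≥k} 1/(1+λ_i), and
Bartlett χ²_k = −(N−1−(p+g)/2)·ln Λ_k with df (p−k+1)(g−k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import SingularityError

__all__ = [
    "DFAModel",
    "ClassificationTable",
    "ManovaResult",
    "BootstrapResult",
    "standardized_residual_scores",
    "canonical_stats_from_eigenvalues",
    "manova_screen",
    "fit_dfa",
    "classify",
    "classification_table",
    "leave_one_out_cv",
    "bootstrap_dfa",
    "structure_matrix_report",
]

Priors = Literal["proportional", "equal"]


# ---------------------------------------------------------------------------
# predictor preparation


def standardized_residual_scores(
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Residualize each predictor on the covariates and standardize.

    Each column is regressed (OLS with intercept) on the covariate
    columns; the residuals are divided by their sample SD, yielding
    columns with mean 0 and SD 1 that are exactly orthogonal to every
    covariate. With no covariates this reduces to plain z-scoring.

    Raises ``ValueError`` naming the column if a predictor is constant.
    """
    X = predictors.to_numpy(dtype=float)
    n = X.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0, ddof=1)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    for j, column in enumerate(predictors.columns):
        if sd[j] <= 1e-10 * scale[j]:
            raise ValueError(f"predictor {column!r} is constant after residualization")
    return pd.DataFrame(resid / sd, columns=predictors.columns, index=predictors.index)


# ---------------------------------------------------------------------------
# scatter matrices


def _as_matrix(predictors) -> np.ndarray:
    X = predictors.to_numpy(dtype=float) if hasattr(predictors, "to_numpy") else np.asarray(
        predictors, dtype=float
    )
    if X.ndim != 2:
        raise ValueError("predictors must be a 2-D matrix")
    return X


def _group_stats(X: np.ndarray, groups: Sequence) -> tuple[list, np.ndarray, np.ndarray]:
    labels = sorted(set(groups))
    groups = np.asarray(groups)
    sizes = np.array([int((groups == g).sum()) for g in labels])
    means = np.vstack([X[groups == g].mean(axis=0) for g in labels])
    return labels, sizes, means


def _scatter(X: np.ndarray, groups: Sequence):
    labels, sizes, means = _group_stats(X, groups)
    groups = np.asarray(groups)
    p = X.shape[1]
    W = np.zeros((p, p))
    for g, mu in zip(labels, means):
        centred = X[groups == g] - mu
        W += centred.T @ centred
    grand = X.mean(axis=0)
    B = (means - grand).T @ (sizes[:, None] * (means - grand))
    return labels, sizes, means, grand, W, B


# ---------------------------------------------------------------------------
# MANOVA screen


@dataclass(frozen=True)
class ManovaResult:
    wilks: float
    f_stat: float
    df1: float
    df2: float
    p_value: float


def manova_screen(predictors, groups) -> ManovaResult:
    """One-way MANOVA: overall group difference via Wilks' Λ and Rao's F.

    Λ = det(W)/det(W+B); Rao's approximation maps Λ to an F statistic
    with df1 = p·q and df2 = w·t − (p·q−2)/2 where q = g−1,
    w = N−1−(p+q+1)/2 and t = sqrt((p²q²−4)/(p²+q²−5)) (t = 1 when the
    denominator vanishes). Exact for g = 2 (Hotelling's T²).
    """
    X = _as_matrix(predictors)
    labels, sizes, _, _, W, B = _scatter(X, groups)
    if len(labels) < 2 or min(sizes) < 2:
        raise ValueError("MANOVA needs at least 2 groups with 2 cases each")
    n, p = X.shape
    q = len(labels) - 1
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularityError(
            "singular within-group scatter in MANOVA; "
            "reduce the number of predictors or pool groups"
        )
    wilks = math.exp(logdet_w - logdet_t)
    denom = p**2 + q**2 - 5
    t = math.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = wilks ** (1 / t)
    f_stat = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(wilks, f_stat, df1, df2, p_value)


# ---------------------------------------------------------------------------
# the discriminant model


@dataclass
class DFAModel:
    """A fitted canonical discriminant-function analysis."""

    groups: list
    group_sizes: np.ndarray
    priors: np.ndarray
    predictor_names: list[str]
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    canonical_correlations: np.ndarray
    wilks_lambda: np.ndarray
    chi2: np.ndarray
    chi2_df: np.ndarray
    chi2_p: np.ndarray
    raw_coefficients: np.ndarray  # p × m, scores have pooled within-group var 1
    raw_constants: np.ndarray  # m, centres scores at the grand mean
    standardized_coefficients: np.ndarray  # p × m
    structure_matrix: np.ndarray  # p × m pooled within-group correlations
    centroids: np.ndarray  # g × m
    classification_coefficients: np.ndarray  # p × g  (Fisher linear functions)
    classification_constants: np.ndarray  # g
    group_means: np.ndarray = field(repr=False)
    pooled_cov: np.ndarray = field(repr=False)

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    def scores(self, predictors) -> np.ndarray:
        """Discriminant scores (n × m) for a predictor matrix."""
        X = _as_matrix(predictors)
        return X @ self.raw_coefficients + self.raw_constants

    def to_dict(self) -> dict:
        return {
            "groups": list(map(str, self.groups)),
            "group_sizes": self.group_sizes.tolist(),
            "priors": self.priors.tolist(),
            "predictors": self.predictor_names,
            "eigenvalues": self.eigenvalues.tolist(),
            "pct_variance": self.pct_variance.tolist(),
            "canonical_correlations": self.canonical_correlations.tolist(),
            "wilks_lambda": self.wilks_lambda.tolist(),
            "chi2": self.chi2.tolist(),
            "chi2_df": self.chi2_df.tolist(),
            "chi2_p": self.chi2_p.tolist(),
            "raw_coefficients": self.raw_coefficients.tolist(),
            "raw_constants": self.raw_constants.tolist(),
            "standardized_coefficients": self.standardized_coefficients.tolist(),
            "structure_matrix": self.structure_matrix.tolist(),
            "centroids": self.centroids.tolist(),
            "classification_coefficients": self.classification_coefficients.tolist(),
            "classification_constants": self.classification_constants.tolist(),
        }


def canonical_stats_from_eigenvalues(
    eigenvalues: Sequence[float], n_cases: int | None = None, n_predictors: int | None = None,
    n_groups: int | None = None,
) -> dict[str, np.ndarray]:
    """The identity layer of the canonical analysis: derive canonical
    correlations, Wilks' Λ and percent variance (and, when N/p/g are
    given, Bartlett χ² with df) from a set of eigenvalues alone.

    canonical_correlation_i = sqrt(λ_i/(1+λ_i));
    Λ_k = Π_{i≥k} 1/(1+λ_i); pct_i = 100·λ_i/Σλ.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    m = lam.size
    out = {
        "canonical_correlations": np.sqrt(lam / (1 + lam)),
        "wilks_lambda": np.array([np.prod(1.0 / (1 + lam[k:])) for k in range(m)]),
        "pct_variance": 100 * lam / lam.sum(),
    }
    if n_cases is not None and n_predictors is not None and n_groups is not None:
        multiplier = n_cases - 1 - (n_predictors + n_groups) / 2
        out["chi2"] = -multiplier * np.log(out["wilks_lambda"])
        out["chi2_df"] = np.array(
            [(n_predictors - k) * (n_groups - 1 - k) for k in range(m)], dtype=int
        )
    return out


def _priors_vector(priors: Priors, sizes: np.ndarray) -> np.ndarray:
    if priors == "proportional":
        return sizes / sizes.sum()
    if priors == "equal":
        return np.full(len(sizes), 1.0 / len(sizes))
    raise ValueError(f"unknown priors {priors!r}")


def fit_dfa(
    predictors,
    groups,
    priors: Priors = "proportional",
    predictor_names: Sequence[str] | None = None,
) -> DFAModel:
    """Fit the canonical discriminant analysis.

    Solves the generalized eigenproblem B·a = λ·W·a; the min(g−1, p)
    leading eigenvalues are the between/within variance ratios of the
    discriminant functions. Coefficients are scaled so scores have
    pooled within-group variance 1; signs are fixed so each function's
    largest-magnitude structure loading is positive.
    """
    X = _as_matrix(predictors)
    n, p = X.shape
    if predictor_names is None:
        predictor_names = (
            list(predictors.columns)
            if hasattr(predictors, "columns")
            else [f"x{j}" for j in range(p)]
        )
    labels, sizes, means, grand, W, B = _scatter(X, groups)
    g = len(labels)
    if n <= p + g - 1:
        raise SingularityError(
            f"N={n} cases cannot support p={p} predictors with g={g} groups; "
            "reduce the predictor set"
        )
    try:
        # eigh solves the symmetric-definite pair (B, W): real spectrum,
        # eigenvectors a with aᵀWa = 1
        eigvals, eigvecs = linalg.eigh(B, W)
    except linalg.LinAlgError as err:
        raise SingularityError(f"singular within-group scatter: {err}") from None
    order = np.argsort(eigvals)[::-1]
    m = min(g - 1, p)
    lam = np.clip(eigvals[order][:m], 0.0, None)
    A = eigvecs[:, order][:, :m]

    df_within = n - g
    pooled_cov = W / df_within
    # aᵀWa = 1  ⇒  pooled within variance of scores = 1/df_within
    A = A * math.sqrt(df_within)

    pooled_sd = np.sqrt(np.diag(pooled_cov))
    structure = (pooled_cov @ A) / pooled_sd[:, None]
    # deterministic sign: dominant loading of each function positive
    for i in range(m):
        j = int(np.argmax(np.abs(structure[:, i])))
        if structure[j, i] < 0:
            A[:, i] *= -1
            structure[:, i] *= -1
    constants = -grand @ A
    standardized = A * pooled_sd[:, None]
    centroids = (means @ A) + constants

    canonical_corr = np.sqrt(lam / (1 + lam))
    wilks = np.array([np.prod(1.0 / (1 + lam[k:])) for k in range(m)])
    multiplier = n - 1 - (p + g) / 2
    chi2 = -multiplier * np.log(wilks)
    chi2_df = np.array([(p - k) * (g - 1 - k) for k in range(m)], dtype=int)
    chi2_p = stats.chi2.sf(chi2, chi2_df)
    total = lam.sum()
    pct = 100 * lam / total if total > 0 else np.zeros(m)

    prior_vec = _priors_vector(priors, sizes)
    try:
        solve = linalg.cho_factor(pooled_cov)
    except linalg.LinAlgError as err:
        raise SingularityError(f"singular pooled covariance: {err}") from None
    class_coef = linalg.cho_solve(solve, means.T)  # p × g
    class_const = -0.5 * np.einsum("jg,jg->g", class_coef, means.T) + np.log(prior_vec)

    return DFAModel(
        groups=labels,
        group_sizes=sizes,
        priors=prior_vec,
        predictor_names=list(predictor_names),
        eigenvalues=lam,
        pct_variance=pct,
        canonical_correlations=canonical_corr,
        wilks_lambda=wilks,
        chi2=chi2,
        chi2_df=chi2_df,
        chi2_p=chi2_p,
        raw_coefficients=A,
        raw_constants=constants,
        standardized_coefficients=standardized,
        structure_matrix=structure,
        centroids=centroids,
        classification_coefficients=class_coef,
        classification_constants=class_const,
        group_means=means,
        pooled_cov=pooled_cov,
    )


def classify(model: DFAModel, predictors) -> np.ndarray:
    """Assign each row to the group with the highest Fisher classification
    score (equivalently the smallest prior-adjusted Mahalanobis distance
    under the pooled covariance). Ties break to the group earliest in the
    model's fixed label order."""
    X = _as_matrix(predictors)
    if X.shape[1] != len(model.predictor_names):
        raise ValueError(
            f"predictor dimension {X.shape[1]} does not match model "
            f"({len(model.predictor_names)})"
        )
    scores = X @ model.classification_coefficients + model.classification_constants
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: fixed-order tie-break
    return np.array([model.groups[i] for i in idx])


# ---------------------------------------------------------------------------
# classification tables


@dataclass
class ClassificationTable:
    """g×g confusion counts with accuracies and a Pearson χ²."""

    groups: list
    counts: np.ndarray  # rows: original group, columns: predicted
    per_group_accuracy: np.ndarray  # percent
    overall_accuracy: float  # percent
    chi2: float
    df: int
    p_value: float
    mode: str = "apparent"
    n_unclassified: int = 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.groups, columns=self.groups)
        frame.index.name = "original"
        frame.columns.name = "predicted"
        return frame


def classification_table(
    labels_true,
    labels_pred,
    groups: Sequence | None = None,
    mode: str = "apparent",
    n_unclassified: int = 0,
) -> ClassificationTable:
    """Build the confusion table with per-group/overall accuracy and the
    Pearson χ² of the g×g contingency table (expected counts from the
    row/column margins, df = (g−1)²)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    if groups is None:
        groups = sorted(set(labels_true))
    groups = list(groups)
    unseen = set(labels_pred) - set(groups)
    if unseen:
        raise ValueError(f"predicted label(s) not in group set: {sorted(unseen)}")
    g = len(groups)
    index = {label: i for i, label in enumerate(groups)}
    counts = np.zeros((g, g), dtype=int)
    for t, q in zip(labels_true, labels_pred):
        counts[index[t], index[q]] += 1
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    total = counts.sum()
    expected = np.outer(row, col) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(cells.sum())
    df = (g - 1) ** 2
    p_value = float(stats.chi2.sf(chi2, df))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = np.where(row > 0, 100.0 * np.diag(counts) / row, np.nan)
    overall = 100.0 * np.trace(counts) / total
    return ClassificationTable(
        groups=groups,
        counts=counts,
        per_group_accuracy=per_group,
        overall_accuracy=float(overall),
        chi2=chi2,
        df=df,
        p_value=p_value,
        mode=mode,
        n_unclassified=n_unclassified,
    )


def _fisher_functions(X, groups, priors: Priors):
    """Lightweight classification-only fit (means + pooled covariance)."""
    labels, sizes, means = _group_stats(X, groups)
    groups_arr = np.asarray(groups)
    p = X.shape[1]
    W = np.zeros((p, p))
    for g, mu in zip(labels, means):
        centred = X[groups_arr == g] - mu
        W += centred.T @ centred
    pooled = W / (X.shape[0] - len(labels))
    prior_vec = _priors_vector(priors, sizes)
    solve = linalg.cho_factor(pooled)
    coef = linalg.cho_solve(solve, means.T)
    const = -0.5 * np.einsum("jg,jg->g", coef, means.T) + np.log(prior_vec)
    return labels, coef, const


def leave_one_out_cv(predictors, groups, priors: Priors = "proportional") -> ClassificationTable:
    """Leave-one-out cross-validated classification.

    Each case is held out in turn; the classification rule (group means,
    pooled covariance, priors) is refit on the remaining N−1 cases and
    the held-out case classified by it. Folds with a singular scatter
    leave their case unclassified; such cases are counted, not silently
    dropped.
    """
    X = _as_matrix(predictors)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    sizes = {g: int((groups == g).sum()) for g in labels}
    if min(sizes.values()) < 3:
        import warnings

        warnings.warn("LOOCV with a group of fewer than 3 cases is degenerate", stacklevel=2)
    kept_true, kept_pred = [], []
    n_unclassified = 0
    mask = np.ones(len(groups), dtype=bool)
    for i in range(len(groups)):
        mask[i] = False
        try:
            fold_labels, coef, const = _fisher_functions(X[mask], groups[mask], priors)
            scores = X[i] @ coef + const
            kept_pred.append(fold_labels[int(np.argmax(scores))])
            kept_true.append(groups[i])
        except (linalg.LinAlgError, SingularityError, ValueError):
            n_unclassified += 1
        finally:
            mask[i] = True
    return classification_table(
        kept_true, kept_pred, groups=labels, mode="leave_one_out", n_unclassified=n_unclassified
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    n_boot: int
    n_dropped: int
    eigenvalues: np.ndarray  # kept replicates × m
    canonical_correlations: np.ndarray
    accuracy: np.ndarray  # apparent accuracy per replicate, percent
    eigenvalue_ci: np.ndarray  # m × 2 percentile bounds
    canonical_correlation_ci: np.ndarray
    accuracy_ci: np.ndarray  # length 2

    def to_frame(self) -> pd.DataFrame:
        m = self.eigenvalues.shape[1]
        data = {f"eigenvalue_{i + 1}": self.eigenvalues[:, i] for i in range(m)}
        data.update(
            {f"canonical_correlation_{i + 1}": self.canonical_correlations[:, i] for i in range(m)}
        )
        data["apparent_accuracy_pct"] = self.accuracy
        return pd.DataFrame(data)


def bootstrap_dfa(
    predictors,
    groups,
    n_boot: int = 1000,
    seed: int | None = None,
    priors: Priors = "proportional",
) -> BootstrapResult:
    """Stratified case bootstrap of the DFA.

    Cases are resampled with replacement within group (group sizes fixed),
    the model refit on each replicate, and percentile 95% intervals
    returned for the eigenvalues, canonical correlations and apparent
    accuracy. Replicates with singular scatter are dropped and counted; a
    warning is raised when more than 20% are dropped.
    """
    X = _as_matrix(predictors)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    rng = np.random.default_rng(seed)
    group_idx = {g: np.flatnonzero(groups == g) for g in labels}
    eigs, corrs, accs = [], [], []
    n_dropped = 0
    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(group_idx[g], size=len(group_idx[g]), replace=True) for g in labels]
        )
        try:
            model = fit_dfa(X[take], groups[take], priors=priors)
            pred = classify(model, X[take])
        except SingularityError:
            n_dropped += 1
            continue
        eigs.append(model.eigenvalues)
        corrs.append(model.canonical_correlations)
        accs.append(100.0 * float((pred == groups[take]).mean()))
    if n_boot and n_dropped > 0.2 * n_boot:
        import warnings

        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates were singular", stacklevel=2)
    eigs_arr = np.array(eigs)
    corrs_arr = np.array(corrs)
    accs_arr = np.array(accs)
    pct = [2.5, 97.5]
    return BootstrapResult(
        n_boot=n_boot,
        n_dropped=n_dropped,
        eigenvalues=eigs_arr,
        canonical_correlations=corrs_arr,
        accuracy=accs_arr,
        eigenvalue_ci=np.percentile(eigs_arr, pct, axis=0).T,
        canonical_correlation_ci=np.percentile(corrs_arr, pct, axis=0).T,
        accuracy_ci=np.percentile(accs_arr, pct),
    )


# ---------------------------------------------------------------------------
# structure-matrix reporting


def structure_matrix_report(
    model: DFAModel, threshold: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full and display-filtered structure matrices.

    The filtered form masks (NaN) loadings with |r| < threshold — small
    loadings are conventionally treated as uninterpretable at modest
    sample sizes. The full matrix is always retained.
    """
    columns = [f"function_{i + 1}" for i in range(model.n_functions)]
    full = pd.DataFrame(model.structure_matrix, index=model.predictor_names, columns=columns)
    filtered = full.where(full.abs() >= threshold)
    return full, filtered
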