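"""Leave-one-out max-margin classification with nested feature selection.

The prediction pipeline treats each subject as a point in the space of
(frequency, region-pair) PLV features and separates patients (+1) from
controls (-1) with a soft-margin linear SVM. Feature selection is nested
inside leave-one-out cross-validation (LOOCV): at each fold, features are
ranked on the training subjects only by the area under the ROC curve (AUR)
of each single feature, folded as max(AUC, 1-AUC) so that discrimination in
either direction counts; the top-k features are kept and the classifier is
fit on the standardized training columns. The held-out subject's signed
Euclidean distance to the decision boundary, (w.x + b)/||w||, serves as the
classification confidence (positive = patient side).

Significance of an observed accuracy is assessed against a null
distribution built by shuffling the group labels and re-running the entire
nested procedure (ranking included) per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.svm import SVC

from megsync.grid import FrequencyGrid, BAND_NAMES
from megsync.connectivity import ConnectivityTensor

PATIENT, CONTROL = 1, -1


@dataclass
class FeatureSet:
    """Subjects x features PLV matrix with labels and column provenance.

    ``feature_labels`` holds one (frequency_index, pair_index) tuple per
    column, tracing each feature back to its tensor cell.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_labels: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.size:
            raise ValueError("label count does not match subject count")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")
        present = set(np.unique(self.labels))
        if not present <= {PATIENT, CONTROL}:
            raise ValueError(f"labels must be in {{+1, -1}}, got {present}")
        if len(present) < 2:
            raise ValueError("both classes must be present")
        if len(self.feature_labels) != self.matrix.shape[1]:
            raise ValueError("feature_labels length does not match column count")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def features_from_tensor(
    tensor: ConnectivityTensor,
    labels: np.ndarray,
    freq_indices: np.ndarray | list[int],
) -> FeatureSet:
    """Pool tensor cells at the given frequency indices into a FeatureSet.

    Columns are ordered frequency-major, pair-minor.
    """
    freq_indices = np.asarray(freq_indices, dtype=int)
    n_p = tensor.plv.shape[2]
    cols = tensor.plv[:, freq_indices, :].reshape(tensor.n_subjects, -1)
    feature_labels = [(int(fi), p) for fi in freq_indices for p in range(n_p)]
    return FeatureSet(matrix=cols, labels=labels, feature_labels=feature_labels)


@dataclass
class LinearModel:
    """Linear decision boundary w.x + b = 0 in standardized feature space."""

    weights: np.ndarray
    bias: float
    c: float
    column_mean: np.ndarray
    column_scale: np.ndarray

    def decision(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.column_mean) / self.column_scale
        return z @ self.weights + self.bias

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        """Signed Euclidean distance to the boundary (positive = patient)."""
        return self.decision(x) / np.linalg.norm(self.weights)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x) > 0, PATIENT, CONTROL)


@dataclass
class CVOutcome:
    """Per-fold LOOCV records plus aggregate accuracies.

    ``distances`` are signed Euclidean distances of the held-out subjects;
    ``selected`` lists the original column indices kept at each fold.
    """

    true_labels: np.ndarray
    predicted: np.ndarray
    distances: np.ndarray
    selected: list[np.ndarray]
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        y, p = self.true_labels, self.predicted
        pos, neg = y == PATIENT, y == CONTROL
        tp = int(np.sum(p[pos] == PATIENT))
        tn = int(np.sum(p[neg] == CONTROL))
        self.sensitivity = tp / max(pos.sum(), 1)
        self.specificity = tn / max(neg.sum(), 1)
        self.accuracy = (tp + tn) / y.size


@dataclass
class NullDistribution:
    """Accuracies under label permutation and the add-one p-value."""

    accuracies: np.ndarray
    observed: float
    p_value: float


# ---------------------------------------------------------------------------
# feature ranking


def auc_separability(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """Direction-free ROC area of one feature: max(AUC, 1-AUC) in [0.5, 1].

    AUC is the Mann-Whitney probability that a patient value exceeds a
    control value, with ties counting 1/2 (computed via average ranks). A
    constant column scores exactly 0.5.
    """
    auc = _auc_columns(np.asarray(feature_column, float).reshape(-1, 1), labels)[0]
    return float(max(auc, 1.0 - auc))


def _auc_columns(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Unfolded Mann-Whitney AUC of every column (vectorized rank method)."""
    pos = labels == PATIENT
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sp_stats.rankdata(x, axis=0)  # average ranks handle ties
    rank_sum_pos = ranks[pos].sum(axis=0)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def rank_features(features: FeatureSet) -> np.ndarray:
    """Column indices sorted by folded AUR, descending.

    Ties break by original column order (lower frequency, then lower pair
    index, given frequency-major column layout), so rankings are
    deterministic.
    """
    auc = _auc_columns(features.matrix, features.labels)
    folded = np.maximum(auc, 1.0 - auc)
    # stable sort on negated score preserves column order within ties
    return np.argsort(-folded, kind="stable")


# ---------------------------------------------------------------------------
# model fitting


def fit_linear_maxmargin(
    x: np.ndarray, y: np.ndarray, c: float = 1.0, standardize: bool = True
) -> LinearModel:
    """Soft-margin linear SVM; +1 side of the boundary is the patient class.

    Columns are z-scored with the statistics of ``x`` itself (training
    data); pass ``standardize=False`` to fit in raw coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    z = (x - mean) / scale
    svm = SVC(kernel="linear", C=c)
    svm.fit(z, y)
    # sklearn orders classes [-1, +1], so decision > 0 already means patient
    return LinearModel(
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        c=c,
        column_mean=mean,
        column_scale=scale,
    )


# ---------------------------------------------------------------------------
# cross-validation


def loocv(
    features: FeatureSet,
    k_best: int | None = None,
    c: float = 1.0,
) -> CVOutcome:
    """Leave-one-out CV with per-fold AUR ranking and top-k selection.

    The held-out subject never enters ranking, standardization or fitting.
    ``k_best=None`` keeps every feature of the set (the per-wavelet and
    per-band schemes); k larger than the available feature count is clamped
    with a warning.
    """
    m = features.n_subjects
    if m < 4:
        raise ValueError("need at least 4 subjects for leave-one-out CV")
    if k_best is not None:
        if k_best < 1:
            raise ValueError("k_best must be >= 1")
        if k_best > features.n_features:
            import warnings

            warnings.warn(
                f"k_best={k_best} exceeds {features.n_features} features; clamped",
                stacklevel=2,
            )
            k_best = features.n_features
    outcomes = _loocv_curve(features, [k_best], c)
    return outcomes[0]


def _loocv_curve(
    features: FeatureSet, k_values: list[int | None], c: float
) -> list[CVOutcome]:
    """Shared LOOCV engine: rank once per fold, refit for every k."""
    m = features.n_subjects
    x, y = features.matrix, features.labels
    preds = {k: np.empty(m, dtype=int) for k in range(len(k_values))}
    dists = {k: np.empty(m) for k in range(len(k_values))}
    selected: dict[int, list[np.ndarray]] = {k: [] for k in range(len(k_values))}
    for j in range(m):
        train = np.ones(m, dtype=bool)
        train[j] = False
        train_fs = FeatureSet(
            matrix=x[train], labels=y[train], feature_labels=features.feature_labels
        )
        order = rank_features(train_fs)
        for ki, k_best in enumerate(k_values):
            keep = order if k_best is None else order[: min(k_best, len(order))]
            model = fit_linear_maxmargin(x[train][:, keep], y[train], c)
            dists[ki][j] = model.signed_distance(x[j, keep])[0]
            preds[ki][j] = PATIENT if dists[ki][j] > 0 else CONTROL
            selected[ki].append(np.sort(keep))
    return [
        CVOutcome(
            true_labels=y.copy(),
            predicted=preds[ki],
            distances=dists[ki],
            selected=selected[ki],
        )
        for ki in range(len(k_values))
    ]


def accuracy_by_wavelet(
    tensor: ConnectivityTensor, labels: np.ndarray, c: float = 1.0
) -> dict[int, CVOutcome]:
    """One LOOCV per frequency, using all pairs at that frequency."""
    if tensor.plv.shape[1] < 2:
        raise ValueError("need at least 2 frequencies")
    out = {}
    for fi in range(tensor.plv.shape[1]):
        fs = features_from_tensor(tensor, labels, [fi])
        out[fi] = loocv(fs, k_best=None, c=c)
    return out


def accuracy_by_band(
    tensor: ConnectivityTensor,
    labels: np.ndarray,
    c: float = 1.0,
    bands: tuple[str, ...] = BAND_NAMES,
) -> dict[str, CVOutcome]:
    """One LOOCV per canonical band, pooling all (frequency, pair) features."""
    grid = FrequencyGrid(tensor.frequencies_hz)
    out = {}
    for band in bands:
        idx = grid.band_indices(band)
        if idx.size == 0:
            raise ValueError(f"band {band!r} contains no grid frequencies")
        fs = features_from_tensor(tensor, labels, idx)
        out[band] = loocv(fs, k_best=None, c=c)
    return out


def accuracy_vs_k(
    features: FeatureSet,
    k_max: int = 100,
    c: float = 1.0,
) -> tuple[list[CVOutcome], int]:
    """LOOCV accuracy curves for k = 1..k_max best-ranked features.

    Returns the per-k outcomes and the k (1-based) achieving maximal
    accuracy, ties resolving to the smaller k.
    """
    if k_max > features.n_features:
        raise ValueError(f"k_max={k_max} exceeds {features.n_features} features")
    ks: list[int | None] = list(range(1, k_max + 1))
    outcomes = _loocv_curve(features, ks, c)
    accs = np.array([o.accuracy for o in outcomes])
    best_k = int(np.argmax(accs)) + 1  # argmax takes the first (smallest k) tie
    return outcomes, best_k


# ---------------------------------------------------------------------------
# permutation significance


def permutation_null(
    features: FeatureSet,
    k_best: int | None,
    c: float,
    n_perm: int,
    seed: int | np.random.Generator,
    observed_accuracy: float | None = None,
) -> NullDistribution:
    """Label-shuffle null for LOOCV accuracy.

    Every permutation re-runs the full nested procedure (per-fold ranking
    included) on shuffled labels. p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if observed_accuracy is None:
        observed_accuracy = loocv(features, k_best=k_best, c=c).accuracy
    null = np.empty(n_perm)
    y = features.labels
    for i in range(n_perm):
        perm = FeatureSet(
            matrix=features.matrix,
            labels=rng.permutation(y),
            feature_labels=features.feature_labels,
        )
        null[i] = loocv(perm, k_best=k_best, c=c).accuracy
    p = (1 + int(np.sum(null >= observed_accuracy))) / (n_perm + 1)
    return NullDistribution(accuracies=null, observed=observed_accuracy, p_value=p)


# ---------------------------------------------------------------------------
# confidence and robustness


def confidence_score_correlation(
    outcomes_by_k: dict[int, CVOutcome] | list[CVOutcome],
    scores: np.ndarray,
    labels: np.ndarray,
) -> dict[int, tuple[float, np.ndarray, np.ndarray]]:
    """Pearson r between patient decision-boundary distances and scores.

    Computed over patients only at each k; a misclassified patient carries a
    negative distance. Returns {k: (r, patient_distances, patient_scores)}.
    Raises if the patient scores have zero variance (r undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    patients = labels == PATIENT
    pat_scores = scores[patients]
    if np.isnan(pat_scores).any():
        raise ValueError("scores missing for some patients")
    if np.std(pat_scores) == 0:
        raise ValueError("patient scores have zero variance; correlation undefined")
    if isinstance(outcomes_by_k, list):
        outcomes_by_k = {k + 1: o for k, o in enumerate(outcomes_by_k)}
    out = {}
    for k, outcome in outcomes_by_k.items():
        d = outcome.distances[patients]
        if np.std(d) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(d, pat_scores)[0, 1])
        out[k] = (r, d, pat_scores)
    return out


def feature_robustness_map(
    outcomes_by_wavelet: dict[int, CVOutcome], n_pairs: int
) -> np.ndarray:
    """Per-pair participation weights in [-1, 0] across folds and wavelets.

    A connection scores -1 in a (fold, wavelet) cell when any feature built
    on it was selected there, 0 otherwise; the map is the mean over all
    cells. -1 = selected everywhere, 0 = never selected.
    """
    weights = np.zeros(n_pairs)
    n_cells = 0
    for outcome in outcomes_by_wavelet.values():
        for keep in outcome.selected:
            pair_cols = np.unique(np.mod(keep, n_pairs))
            weights[pair_cols] -= 1.0
            n_cells += 1
    if n_cells == 0:
        raise ValueError("no completed folds supplied")
    return weights / n_cells
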