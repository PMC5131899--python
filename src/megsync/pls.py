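"""Contrast and behavioural partial least squares on connectivity elements.

The data matrix stacks subjects within groups by "elements" — every
(frequency, region-pair) PLV combination (30 x 4005 = 120,150 at full
scale). Contrast PLS decomposes the deviation of group means from the grand
mean with an SVD, yielding latent variables (LVs): a singular value, a
group contrast (left vector) and per-element saliences (right vector).
Behavioural PLS replaces the group-mean block with the vector of
per-element Pearson correlations against a continuous covariate (one row,
hence a single LV) and reports the overall correlation between the
LV-projected brain scores and the behaviour.

LV significance comes from permutation tests (group relabelling or
behaviour shuffling); element stability from bootstrap resampling of
subjects within groups: the bootstrap ratio (original salience divided by
its bootstrap SE) behaves like a z-score, with |ratio| >= 3 roughly a 95%
confidence statement. Tail statistics count, per frequency, the elements in
the extreme quantiles of the pooled ratio distribution, and pooled-variance
two-sample proportion z-tests compare those counts between frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from megsync.connectivity import ConnectivityTensor

PATIENT, CONTROL = 1, -1


@dataclass
class ElementMatrix:
    """Subjects-within-groups by elements matrix.

    Rows are blocked by group (patients first); columns are ordered
    frequency-major, pair-minor. ``element_labels`` holds (frequency_index,
    pair_index) per column; ``group_sizes`` the per-group row counts in
    block order.
    """

    matrix: np.ndarray
    element_labels: np.ndarray  # (n_elements, 2): freq idx, pair idx
    group_sizes: tuple[int, ...]
    n_frequencies: int
    n_pairs: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != sum(self.group_sizes):
            raise ValueError("row count does not match group sizes")
        if self.matrix.shape[1] != self.n_frequencies * self.n_pairs:
            raise ValueError("column count must equal n_frequencies * n_pairs")

    @property
    def group_slices(self) -> list[slice]:
        out, start = [], 0
        for size in self.group_sizes:
            out.append(slice(start, start + size))
            start += size
        return out


@dataclass
class PLSModel:
    """SVD of the cross-block matrix: one latent variable per component.

    ``left_vectors[:, l]`` is LV l's group contrast (contrast PLS) or, for
    behavioural PLS, a scalar row whose meaning is carried by
    ``overall_correlation``; ``right_vectors[:, l]`` its element saliences.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    cross_block: np.ndarray
    mode: str  # "contrast" | "behavioural"
    overall_correlation: float | None = None
    lv_p_values: np.ndarray | None = None


@dataclass
class BootstrapRatios:
    """Per-element stability ratios: original loading / bootstrap SE.

    Elements whose bootstrap SE is zero are flagged NaN rather than
    infinite. ``loadings`` are the singular-value-weighted saliences s*v of
    the tested LV.
    """

    ratios: np.ndarray
    loadings: np.ndarray
    se: np.ndarray
    n_boot: int
    element_labels: np.ndarray


def build_element_matrix(
    tensor: ConnectivityTensor, groups: np.ndarray
) -> ElementMatrix:
    """Reshape a PLV tensor into the subjects-within-groups by elements form.

    Rows are reordered patients-then-controls (stable within group);
    columns frequency-major. Every subject must carry a group label in
    {+1, -1}.
    """
    groups = np.asarray(groups)
    if groups.size != tensor.n_subjects:
        raise ValueError("one group label per subject required")
    if not set(np.unique(groups)) <= {PATIENT, CONTROL}:
        raise ValueError("group labels must be +1 (patient) or -1 (control)")
    order = np.concatenate(
        [np.flatnonzero(groups == PATIENT), np.flatnonzero(groups == CONTROL)]
    )
    n_sub, n_freq, n_pair = tensor.plv.shape
    matrix = tensor.plv[order].reshape(n_sub, n_freq * n_pair)
    if np.isnan(matrix).any():
        raise ValueError("tensor contains missing values; drop masked frequencies first")
    labels = np.array(
        [(fi, p) for fi in range(n_freq) for p in range(n_pair)], dtype=int
    )
    return ElementMatrix(
        matrix=matrix,
        element_labels=labels,
        group_sizes=(
            int(np.sum(groups == PATIENT)),
            int(np.sum(groups == CONTROL)),
        ),
        n_frequencies=n_freq,
        n_pairs=n_pair,
    )


# ---------------------------------------------------------------------------
# decompositions


def _contrast_cross_block(matrix: np.ndarray, slices: list[slice]) -> np.ndarray:
    """Group means centered on the grand mean (mean-centered task PLS)."""
    means = np.stack([matrix[s].mean(axis=0) for s in slices])
    return means - means.mean(axis=0)


def contrast_pls(em: ElementMatrix) -> PLSModel:
    """Mean-centered PLS of group differences.

    For two groups the centered group-mean matrix has rank one: a single LV
    whose left vector is the (antisymmetric) group contrast and whose right
    vector holds the element saliences.
    """
    if len(em.group_sizes) < 2:
        raise ValueError("contrast PLS needs at least two groups")
    if min(em.group_sizes) < 2:
        raise ValueError("every group needs >= 2 subjects")
    cross = _contrast_cross_block(em.matrix, em.group_slices)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    # orient each LV so the first (patient) block carries the non-positive
    # left weight: elements elevated in patients then load negatively,
    # making the SVD sign deterministic across backends
    for lv in range(s.size):
        if u[0, lv] > u[-1, lv]:
            u[:, lv] *= -1.0
            vt[lv] *= -1.0
    return PLSModel(
        singular_values=s,
        left_vectors=u,
        right_vectors=vt.T,
        cross_block=cross,
        mode="contrast",
    )


def _behaviour_cross_block(matrix: np.ndarray, behaviour: np.ndarray) -> np.ndarray:
    """Per-element Pearson correlations with the behaviour, as a 1 x E row."""
    y = behaviour - behaviour.mean()
    sy = y.std()
    if sy == 0:
        raise ValueError("behaviour has zero variance")
    x = matrix - matrix.mean(axis=0)
    sx = x.std(axis=0)
    sx_safe = np.where(sx == 0, 1.0, sx)
    corr = (x * y[:, None]).mean(axis=0) / (sx_safe * sy)
    corr[sx == 0] = 0.0
    return corr[None, :]


def behavioural_pls(
    em: ElementMatrix, behaviour: np.ndarray, rows: slice | np.ndarray | None = None
) -> PLSModel:
    """PLS against a continuous per-subject covariate.

    ``rows`` restricts the analysis to a subject subset (canonically the
    patient block, e.g. ``em.group_slices[0]``); default uses all rows.
    The cross-block is the row vector of per-element correlations, so there
    is exactly one LV; the model also reports the overall correlation
    between the projected brain scores and the behaviour.
    """
    x = em.matrix if rows is None else em.matrix[rows]
    behaviour = np.asarray(behaviour, dtype=float)
    if behaviour.size != x.shape[0]:
        raise ValueError("behaviour must align with the selected rows")
    if np.isnan(behaviour).any():
        raise ValueError("behaviour contains missing values")
    cross = _behaviour_cross_block(x, behaviour)
    s = float(np.linalg.norm(cross))
    if s == 0:
        v = np.zeros(cross.shape[1])
        overall = 0.0
    else:
        v = cross.ravel() / s
        scores = x @ v
        overall = (
            float(np.corrcoef(scores, behaviour)[0, 1]) if scores.std() > 0 else 0.0
        )
    return PLSModel(
        singular_values=np.array([s]),
        left_vectors=np.array([[1.0]]),
        right_vectors=v[:, None],
        cross_block=cross,
        mode="behavioural",
        overall_correlation=overall,
    )


# ---------------------------------------------------------------------------
# resampling


def lv_permutation_test(
    em: ElementMatrix,
    n_perm: int,
    seed: int | np.random.Generator,
    behaviour: np.ndarray | None = None,
    rows: slice | np.ndarray | None = None,
) -> tuple[np.ndarray, PLSModel]:
    """Permutation p-value per LV: rows across groups, or behaviour shuffled.

    p = (1 + #{permuted s >= observed s}) / (n_perm + 1), compared per LV
    index. Returns (p_values, observed_model).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if behaviour is None:
        observed = contrast_pls(em)
        exceed = np.zeros(observed.singular_values.size)
        n_rows = em.matrix.shape[0]
        for _ in range(n_perm):
            perm = rng.permutation(n_rows)
            shuffled = ElementMatrix(
                matrix=em.matrix[perm],
                element_labels=em.element_labels,
                group_sizes=em.group_sizes,
                n_frequencies=em.n_frequencies,
                n_pairs=em.n_pairs,
            )
            s_perm = contrast_pls(shuffled).singular_values
            exceed += s_perm >= observed.singular_values
    else:
        observed = behavioural_pls(em, behaviour, rows=rows)
        exceed = np.zeros(1)
        for _ in range(n_perm):
            s_perm = behavioural_pls(
                em, rng.permutation(behaviour), rows=rows
            ).singular_values
            exceed += s_perm >= observed.singular_values
    p = (1.0 + exceed) / (n_perm + 1.0)
    observed.lv_p_values = p
    return p, observed


def bootstrap_ratios(
    em: ElementMatrix,
    n_boot: int,
    seed: int | np.random.Generator,
    behaviour: np.ndarray | None = None,
    rows: slice | np.ndarray | None = None,
    lv: int = 0,
    max_redraws: int = 100,
) -> BootstrapRatios:
    """Bootstrap stability of element loadings for one LV.

    Subjects are resampled with replacement within their group (behavioural
    mode: within the analysed subset); each resample's loadings s*v are
    sign-aligned to the original salience vector (flipped when their dot
    product is negative) before accumulating. Degenerate resamples that
    collapse a group to a single distinct subject are redrawn, up to
    ``max_redraws`` per resample.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 (bootstrap SE undefined otherwise)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if behaviour is None:
        original = contrast_pls(em)
        slices = em.group_slices
    else:
        original = behavioural_pls(em, behaviour, rows=rows)
        x_rows = em.matrix if rows is None else em.matrix[rows]
        behaviour = np.asarray(behaviour, dtype=float)

    v0 = original.right_vectors[:, lv]
    loadings0 = original.singular_values[lv] * v0

    boot = np.empty((n_boot, v0.size))
    for b in range(n_boot):
        for _ in range(max_redraws):
            if behaviour is None:
                idx = np.concatenate(
                    [
                        rng.integers(s.start, s.stop, size=s.stop - s.start)
                        for s in slices
                    ]
                )
                degenerate = any(
                    np.unique(idx[(idx >= s.start) & (idx < s.stop)]).size < 2
                    for s in slices
                )
            else:
                idx = rng.integers(0, x_rows.shape[0], size=x_rows.shape[0])
                degenerate = np.unique(idx).size < 2 or behaviour[idx].std() == 0
            if not degenerate:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        if behaviour is None:
            resample = ElementMatrix(
                matrix=em.matrix[idx],
                element_labels=em.element_labels,
                group_sizes=em.group_sizes,
                n_frequencies=em.n_frequencies,
                n_pairs=em.n_pairs,
            )
            model = contrast_pls(resample)
        else:
            model = behavioural_pls(
                ElementMatrix(
                    matrix=x_rows[idx],
                    element_labels=em.element_labels,
                    group_sizes=(x_rows.shape[0],),
                    n_frequencies=em.n_frequencies,
                    n_pairs=em.n_pairs,
                ),
                behaviour[idx],
            )
        vb = model.right_vectors[:, lv]
        if vb @ v0 < 0:
            vb = -vb
        boot[b] = model.singular_values[lv] * vb

    se = boot.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = loadings0 / se
    ratios[se == 0] = np.nan
    return BootstrapRatios(
        ratios=ratios,
        loadings=loadings0,
        se=se,
        n_boot=n_boot,
        element_labels=em.element_labels,
    )


# ---------------------------------------------------------------------------
# tail statistics


def tail_counts(
    ratios: BootstrapRatios, n_frequencies: int, tail_q: float = 0.01
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Per-frequency counts of elements in the pooled ratio tails.

    Thresholds are the (tail_q, 1-tail_q) linear-interpolation quantiles of
    the pooled finite ratios; ties at a threshold fall inside the tail.
    Returns (upper_counts, lower_counts, (lower_thr, upper_thr)).
    """
    if not 0.0 < tail_q < 0.5:
        raise ValueError("tail_q must lie in (0, 0.5)")
    r = ratios.ratios
    finite = np.isfinite(r)
    lo, hi = np.quantile(r[finite], [tail_q, 1.0 - tail_q])
    freq_idx = ratios.element_labels[:, 0]
    upper = np.bincount(
        freq_idx[finite & (r >= hi)], minlength=n_frequencies
    )
    lower = np.bincount(
        freq_idx[finite & (r <= lo)], minlength=n_frequencies
    )
    return upper, lower, (float(lo), float(hi))


def proportion_ztest(
    count1: int, n1: int, count2: int, n2: int
) -> tuple[float, float]:
    """Two-sample proportion z-test, pooled variance, no continuity correction.

    Returns (z, two-sided p). Zero pooled variance gives z = 0, p = 1 by
    convention.
    """
    if not (0 <= count1 <= n1 and 0 <= count2 <= n2):
        raise ValueError("counts must lie within their totals")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    p1, p2 = count1 / n1, count2 / n2
    pooled = (count1 + count2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    p = 2.0 * sp_stats.norm.sf(abs(z))
    return float(z), float(p)


def band_threshold_map(
    ratios: BootstrapRatios,
    band_freq_indices: np.ndarray,
    n_regions: int,
    threshold: float,
    direction: str = "above",
) -> np.ndarray:
    """Band-averaged ratio map thresholded one-sidedly, as a symmetric matrix.

    Per pair, the mean ratio across the band's wavelets is kept when it
    passes the threshold (``direction='above'``: mean > threshold;
    ``'below'``: mean < threshold) and zeroed otherwise.
    """
    band_freq_indices = np.asarray(band_freq_indices, dtype=int)
    if band_freq_indices.size == 0:
        raise ValueError("band contains no frequencies")
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    freq_idx = ratios.element_labels[:, 0]
    pair_idx = ratios.element_labels[:, 1]
    n_p = pair_idx.max() + 1
    means = np.zeros(n_p)
    for p in range(n_p):
        sel = (pair_idx == p) & np.isin(freq_idx, band_freq_indices)
        means[p] = np.nanmean(ratios.ratios[sel])
    keep = means > threshold if direction == "above" else means < threshold
    vals = np.where(keep, means, 0.0)
    mat = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    mat[iu, ju] = vals
    mat[ju, iu] = vals
    return mat
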