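"""Constant-Q wavelet decomposition and phase-locking values (PLV).

The time-frequency representation uses a complex Morlet wavelet whose
envelope width scales inversely with frequency so that every analysis
frequency sees the same number of oscillation cycles (constant Q). The
instantaneous phase of a signal at (time tau, frequency f) is the angle of
its wavelet coefficient W_x(tau, f); the PLV of a signal pair at frequency f
is the modulus of the time-averaged unit phasor of their phase difference,

    PLV_{x,y}(f) = | <exp(i * (phi_x - phi_y))>_tau |  in [0, 1],

computed within each epoch over edge-valid samples and then averaged
arithmetically across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from megsync.grid import FrequencyGrid

#: Default wavelet width in cycles. Balances edge loss at the lowest
#: frequencies within 10 s epochs against frequency resolution.
DEFAULT_N_CYCLES = 7.0

#: Gaussian envelope truncation, in standard deviations, for both the kernel
#: support and the edge-validity mask.
_GAUSS_TRUNC_SD = 3.0


# ---------------------------------------------------------------------------
# pair indexing: row-major over the strict upper triangle


def n_pairs(n_regions: int) -> int:
    """Number of unordered region pairs R*(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def pair_index(i: int, j: int, n_regions: int) -> int:
    """Linear index of the unordered pair (i, j), i < j, row-major."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"need 0 <= i < j < n_regions, got ({i}, {j}, {n_regions})")
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


def pair_from_index(k: int, n_regions: int) -> tuple[int, int]:
    """Inverse of :func:`pair_index`."""
    if not (0 <= k < n_pairs(n_regions)):
        raise ValueError(f"pair index {k} out of range for {n_regions} regions")
    i = 0
    # row lengths are (R-1), (R-2), ...: walk rows until k falls inside one
    row_len = n_regions - 1
    while k >= row_len:
        k -= row_len
        i += 1
        row_len -= 1
    return i, i + 1 + k


def pair_list(n_regions: int) -> np.ndarray:
    """All unordered pairs as an (n_pairs, 2) int array in index order."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return np.column_stack([iu, ju])


# ---------------------------------------------------------------------------
# wavelet transform


@dataclass
class WaveletCoefficients:
    """Complex coefficients W(tau, f) with an edge-validity mask.

    ``values`` and ``valid`` have shape (n_frequencies, n_samples). Samples
    within half the wavelet support of either epoch boundary are marked
    invalid; the masked fraction grows toward lower frequencies.
    """

    values: np.ndarray
    valid: np.ndarray
    frequencies_hz: np.ndarray
    sampling_rate_hz: float
    n_cycles: float


def _morlet_kernel(f_hz: float, fs: float, n_cycles: float) -> np.ndarray:
    """Zero-mean complex Morlet kernel at centre frequency ``f_hz``."""
    sigma_t = n_cycles / (2.0 * np.pi * f_hz)
    half = int(np.floor(_GAUSS_TRUNC_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f_hz * t)
    # enforce exact zero mean so a constant signal is annihilated
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = kernel - env * (kernel.sum() / env.sum())
    # L2 normalisation (amplitude scale is irrelevant for phase/PLV)
    kernel /= np.linalg.norm(kernel)
    return kernel


def wavelet_transform(
    signal: np.ndarray,
    sampling_rate_hz: float,
    grid: FrequencyGrid,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> WaveletCoefficients:
    """Constant-Q complex Morlet transform of a 1-D signal.

    Convolution is 'same'-aligned so row f has one coefficient per input
    sample; coefficients within half the kernel support of either end are
    flagged invalid. A frequency whose kernel exceeds the signal length is
    fully masked rather than rejected.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    n = x.size
    n_freq = len(grid)
    values = np.empty((n_freq, n), dtype=complex)
    valid = np.zeros((n_freq, n), dtype=bool)
    for fi, f in enumerate(grid.frequencies_hz):
        kernel = _morlet_kernel(f, sampling_rate_hz, n_cycles)
        half = (kernel.size - 1) // 2
        if kernel.size > n:
            # epoch shorter than the wavelet: coefficients meaningless
            values[fi] = 0.0
            continue
        fft_n = sp_fft.next_fast_len(n + kernel.size - 1)
        conv = sp_fft.ifft(sp_fft.fft(x, fft_n) * sp_fft.fft(kernel, fft_n))
        values[fi] = conv[half : half + n]
        if 2 * half < n:
            valid[fi, half : n - half] = True
    return WaveletCoefficients(
        values=values,
        valid=valid,
        frequencies_hz=grid.frequencies_hz,
        sampling_rate_hz=float(sampling_rate_hz),
        n_cycles=float(n_cycles),
    )


# ---------------------------------------------------------------------------
# relative phase and PLV


@dataclass
class PhaseSeries:
    """Relative phase in radians wrapped to (-pi, pi], with validity mask."""

    values: np.ndarray
    valid: np.ndarray
    frequencies_hz: np.ndarray


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (-pi, pi]."""
    wrapped = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi  # [-pi, pi)
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def relative_phase(wx: WaveletCoefficients, wy: WaveletCoefficients) -> PhaseSeries:
    """Phase difference angle(W_x * conj(W_y)) per (tau, f).

    Valid masks of the two inputs are intersected.
    """
    if wx.values.shape != wy.values.shape:
        raise ValueError(
            f"shape mismatch: {wx.values.shape} vs {wy.values.shape}"
        )
    dphi = np.angle(wx.values * np.conj(wy.values))
    return PhaseSeries(
        values=_wrap_phase(dphi),
        valid=wx.valid & wy.valid,
        frequencies_hz=wx.frequencies_hz,
    )


def plv(phase_series: PhaseSeries) -> np.ndarray:
    """Per-frequency PLV: |mean over valid tau of exp(i*dphi)| in [0, 1].

    Frequencies with zero valid samples are flagged missing (NaN) rather
    than reported as zero.
    """
    ph = phase_series.values
    mask = phase_series.valid
    counts = mask.sum(axis=1)
    phasors = np.where(mask, np.exp(1j * ph), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(phasors.sum(axis=1)) / counts
    out[counts == 0] = np.nan
    return np.clip(out, 0.0, 1.0)  # NaN propagates


def _epoch_plv_matrix(
    coeffs: list[WaveletCoefficients], pairs: np.ndarray
) -> np.ndarray:
    """PLV for all region pairs within one epoch: (n_freq, n_pairs)."""
    n_freq = coeffs[0].values.shape[0]
    out = np.empty((n_freq, len(pairs)))
    # unit phasors per region, zeroed where invalid
    units = []
    for c in coeffs:
        with np.errstate(invalid="ignore", divide="ignore"):
            u = c.values / np.abs(c.values)
        u[~c.valid] = 0.0
        u[~np.isfinite(u)] = 0.0
        units.append(u)
    valids = [c.valid for c in coeffs]
    for p, (i, j) in enumerate(pairs):
        both = valids[i] & valids[j]
        counts = both.sum(axis=1)
        prod = np.where(both, units[i] * np.conj(units[j]), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.abs(prod.sum(axis=1)) / counts
        v[counts == 0] = np.nan
        out[:, p] = v
    return np.clip(out, 0.0, 1.0)


def subject_connectivity(
    epoched_signals: np.ndarray,
    sampling_rate_hz: float,
    grid: FrequencyGrid,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> np.ndarray:
    """Epoch-averaged PLV slab for one subject: (n_frequencies, n_pairs).

    ``epoched_signals`` has shape (n_epochs, n_regions, n_samples). PLV is
    computed within each epoch for every unordered region pair, then
    averaged arithmetically across epochs (ignoring epochs where a frequency
    is fully masked).
    """
    data = np.asarray(epoched_signals, dtype=float)
    if data.ndim != 3:
        raise ValueError("epoched_signals must have shape (epochs, regions, samples)")
    n_epochs, n_regions, _ = data.shape
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    if n_regions < 2:
        import warnings

        warnings.warn("single region: empty pair set", stacklevel=2)
        return np.empty((len(grid), 0))
    pairs = pair_list(n_regions)
    acc = np.zeros((len(grid), len(pairs)))
    cnt = np.zeros_like(acc)
    for e in range(n_epochs):
        coeffs = [
            wavelet_transform(data[e, r], sampling_rate_hz, grid, n_cycles)
            for r in range(n_regions)
        ]
        epoch_plv = _epoch_plv_matrix(coeffs, pairs)
        ok = np.isfinite(epoch_plv)
        acc[ok] += epoch_plv[ok]
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    return mean


# ---------------------------------------------------------------------------
# connectivity tensor container


@dataclass
class ConnectivityTensor:
    """PLV tensor (n_subjects, n_frequencies, n_pairs) with labels.

    Values lie in [0, 1]; NaN marks frequencies that were fully edge-masked.
    ``pairs`` is the (n_pairs, 2) array of region indices i < j in
    row-major upper-triangle order; ``subject_ids`` aligns with axis 0.
    """

    plv: np.ndarray
    frequencies_hz: np.ndarray
    pairs: np.ndarray
    subject_ids: list[str]
    region_names: list[str]

    def __post_init__(self) -> None:
        self.plv = np.asarray(self.plv, dtype=float)
        if self.plv.ndim != 3:
            raise ValueError("plv must be 3-D (subjects, frequencies, pairs)")
        s, f, p = self.plv.shape
        if f != len(self.frequencies_hz):
            raise ValueError("frequency axis does not match grid")
        if p != len(self.pairs):
            raise ValueError("pair axis does not match pair table")
        if s != len(self.subject_ids):
            raise ValueError("subject axis does not match subject ids")
        finite = self.plv[np.isfinite(self.plv)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("PLV values outside [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.plv.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def matrix(self, subject_idx: int, freq_idx: int) -> np.ndarray:
        """Symmetric region-by-region PLV matrix (unit diagonal)."""
        r = self.n_regions
        m = np.eye(r)
        vals = self.plv[subject_idx, freq_idx]
        iu, ju = self.pairs[:, 0], self.pairs[:, 1]
        m[iu, ju] = vals
        m[ju, iu] = vals
        return m
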