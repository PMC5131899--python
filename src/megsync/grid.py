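"""Logarithmic frequency grid and canonical band partition.

The analysis samples the 1–75 Hz range at 30 points equally spaced on a log
scale (a geometric progression including both endpoints), and groups them
into the five canonical bands delta (1–4 Hz), theta (4–8), alpha (8–14),
beta (14–28) and lower gamma (28–75).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical band partition as (name, low_hz, high_hz). Intervals are
#: half-open [low, high) except the last, which is closed.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 28.0),
    ("gamma", 28.0, 75.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in BANDS)

#: Nominal central frequencies of the five bands, used to pick one
#: representative wavelet per band for tail-count comparisons.
BAND_CENTERS_HZ: dict[str, float] = {
    "delta": 2.0,
    "theta": 6.0,
    "alpha": 11.0,
    "beta": 23.0,
    "gamma": 48.0,
}


def band_of(frequency_hz: float) -> str:
    """Canonical band containing ``frequency_hz``.

    Boundary frequencies belong to the higher band (half-open intervals),
    except the top edge of the last band which is included. Frequencies
    outside [1, 75] are clamped to the nearest band.
    """
    if frequency_hz < BANDS[0][1]:
        return BANDS[0][0]
    for name, low, high in BANDS:
        if low <= frequency_hz < high:
            return name
    return BANDS[-1][0]


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered set of analysis frequencies with band labels.

    Usually built with :func:`make_frequency_grid`; direct construction from
    an arbitrary strictly increasing frequency array is allowed (e.g. a
    single-frequency grid for targeted PLV checks).
    """

    frequencies_hz: np.ndarray
    band_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies_hz, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be positive")
        if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", freqs)
        object.__setattr__(self, "band_labels", tuple(band_of(f) for f in freqs))

    def __len__(self) -> int:
        return int(self.frequencies_hz.size)

    def __iter__(self):
        return iter(self.frequencies_hz)

    def band_indices(self, band: str) -> np.ndarray:
        """Indices of grid points belonging to ``band``."""
        if band not in BAND_NAMES:
            raise ValueError(f"unknown band {band!r}; expected one of {BAND_NAMES}")
        return np.flatnonzero(np.array(self.band_labels) == band)

    def nearest_index(self, target_hz: float) -> int:
        """Index of the grid frequency nearest ``target_hz`` (ties -> lower)."""
        d = np.abs(self.frequencies_hz - target_hz)
        # argmin returns the first (lower-frequency) index on exact ties
        return int(np.argmin(d))


def make_frequency_grid(
    n_points: int = 30, f_min_hz: float = 1.0, f_max_hz: float = 75.0
) -> FrequencyGrid:
    """Geometric frequency progression inclusive of both endpoints.

    The default replicates the study grid: 30 points from 1 to 75 Hz with a
    constant consecutive ratio of 75**(1/29).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if f_min_hz <= 0 or f_max_hz <= f_min_hz:
        raise ValueError("need 0 < f_min_hz < f_max_hz")
    freqs = np.geomspace(f_min_hz, f_max_hz, n_points)
    # pin the endpoints exactly
    freqs[0], freqs[-1] = f_min_hz, f_max_hz
    return FrequencyGrid(freqs)


def band_central_wavelets(
    grid: FrequencyGrid, targets_hz: dict[str, float] | None = None
) -> dict[str, int]:
    """Map each canonical band to the grid index nearest its central frequency.

    Nearest is by absolute difference; ties resolve to the lower frequency.
    Targets outside the grid range clamp to the nearest endpoint.
    """
    targets = BAND_CENTERS_HZ if targets_hz is None else targets_hz
    return {band: grid.nearest_index(f) for band, f in targets.items()}
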