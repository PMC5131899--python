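"""Shared fixtures: reduced-scale study conditions and cached cohorts.

The reduced conditions (12 regions, 12-point log grid 2-60 Hz, 5 epochs of
5 s at 150 Hz, 10 planted alpha pairs with kappa 0.8 vs 0.3) keep every
planted-effect recovery test desk-sized while preserving the structure of
the full-scale analysis.
"""

from __future__ import annotations

import numpy as np
import pytest

from megsync.connectivity import (
    ConnectivityTensor,
    pair_list,
    subject_connectivity,
)
from megsync.grid import FrequencyGrid
from megsync.synthetic import EffectSpec, SimulationConfig, simulate_cohort

#: Ten planted alpha-band pairs over 12 regions.
ALPHA_PAIRS = (
    (0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11),
    (0, 2), (1, 3), (4, 6), (5, 7),
)

ALPHA_HZ = 10.0


def alpha_effect(kappa_a: float = 0.8, kappa_b: float = 0.3) -> EffectSpec:
    return EffectSpec(
        band_center_hz=ALPHA_HZ,
        region_pairs=ALPHA_PAIRS,
        kappa_group_a=kappa_a,
        kappa_group_b=kappa_b,
    )


def reduced_config(
    seed: int,
    n_a: int = 10,
    n_b: int = 10,
    effects: tuple[EffectSpec, ...] | None = None,
    **overrides,
) -> SimulationConfig:
    """Reduced-scale study conditions used throughout the suite."""
    kw = dict(
        n_group_a=n_a,
        n_group_b=n_b,
        n_regions=12,
        n_epochs=5,
        epoch_duration_s=5.0,
        sampling_rate_hz=150.0,
        effects=(alpha_effect(),) if effects is None else effects,
        n_frequencies=12,
        f_min_hz=2.0,
        f_max_hz=60.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def cohort_tensor(config: SimulationConfig) -> tuple[ConnectivityTensor, "pd.DataFrame"]:
    """Signal-path cohort -> PLV tensor."""
    sts, table = simulate_cohort(config)
    grid = config.frequency_grid()
    slabs = np.array(
        [
            subject_connectivity(sts.data[s], config.sampling_rate_hz, grid)
            for s in range(config.n_subjects)
        ]
    )
    tensor = ConnectivityTensor(
        plv=slabs,
        frequencies_hz=grid.frequencies_hz,
        pairs=pair_list(config.n_regions),
        subject_ids=sts.subject_ids,
        region_names=sts.region_names,
    )
    return tensor, table


def single_freq_plv(x: np.ndarray, y: np.ndarray, fs: float, freq: float) -> float:
    """Wavelet PLV of a signal pair at one analysis frequency."""
    from megsync.connectivity import plv, relative_phase, wavelet_transform

    grid = FrequencyGrid(np.array([freq]))
    wx = wavelet_transform(x, fs, grid)
    wy = wavelet_transform(y, fs, grid)
    return float(plv(relative_phase(wx, wy))[0])


@pytest.fixture(scope="session")
def planted_cohort():
    """One cached signal-path cohort with the planted alpha effect."""
    config = reduced_config(seed=0)
    tensor, table = cohort_tensor(config)
    return config, tensor, table
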