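"""Synthetic cohort generator with planted connectivity signatures.

Emulates a two-group resting-state MEG study at the source level: each
subject contributes epoched multi-region time series in which selected
region pairs oscillate at a target frequency with a controllable degree of
phase coupling, on top of 1/f background noise. Clinical covariates
(severity and symptom scores, days since injury) are coupled to the
realized alpha-band connectivity so that every downstream stage —
classification, confidence-score correlation, contrast and behavioural PLS
— has a planted ground truth to recover.

Coupling model
--------------
Each planted pair follows a driver-response scheme in signal space: the
first region carries a narrowband stochastic driver c(t), the second mixes
that driver with an independent process of the same kind,

    x_i(t) = c(t),        x_j(t) = kappa * c(t) + sqrt(1 - kappa^2) * b(t),

where c and b are unit-amplitude oscillations cos(2*pi*f*t + theta +
eta(t)) whose phase jitter eta is a stationary Ornstein-Uhlenbeck process
(SD ``phase_jitter_sd`` radians, correlation time ``phase_jitter_tau_s``).
Because the wavelet transform is linear, the coefficient of x_j at f is the
same mixture of unit phasors, and the expected pairwise PLV has the closed
form

    E[PLV](kappa) = h(kappa)
                  = (1/2pi) Int (kappa + s*cos a) / sqrt(1 + 2*kappa*s*cos a) da,

with s = sqrt(1-kappa^2) (:func:`expected_plv`, evaluated by quadrature).
The map is strictly increasing, 0 at kappa = 0 and 1 at kappa = 1; the
measured PLV at kappa = 0 is the finite-sample noise floor set by the
jitter-driven dephasing rate (~0.13 for 10 s epochs at alpha frequencies
with the default jitter). Amplitudes of the two regions remain essentially
uncorrelated: each signal has near-constant envelope and the common
component carries no amplitude modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from megsync.grid import FrequencyGrid, make_frequency_grid, band_of
from megsync.connectivity import ConnectivityTensor, pair_index, pair_list, n_pairs
from megsync.regions import region_names

#: Stationary SD of the phase jitter (radians); drives the dephasing that
#: sets the kappa=0 finite-sample PLV floor.
DEFAULT_PHASE_JITTER_SD = 2.2
#: Correlation time of the phase jitter (seconds).
DEFAULT_PHASE_JITTER_TAU_S = 0.1

PATIENT, CONTROL = 1, -1

_QUAD_ALPHA = np.linspace(0.0, 2.0 * np.pi, 4097)


def expected_plv(kappa: float) -> float:
    """Asymptotic PLV implied by coupling strength ``kappa``.

    Closed form for the driver-response mixture model (see module docs): a
    trigonometric integral evaluated by trapezoidal quadrature. Strictly
    increasing, expected_plv(0) = 0, expected_plv(1) = 1. Finite-sample
    estimates sit above this by the noise floor.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    if kappa == 1.0:
        return 1.0
    s = np.sqrt(1.0 - kappa**2)
    integrand = (kappa + s * np.cos(_QUAD_ALPHA)) / np.sqrt(
        1.0 + 2.0 * kappa * s * np.cos(_QUAD_ALPHA)
    )
    h = np.trapezoid(integrand, _QUAD_ALPHA) / (2.0 * np.pi)
    return float(min(max(h, 0.0), 1.0))


@dataclass(frozen=True)
class EffectSpec:
    """A planted group-specific coupling effect.

    ``region_pairs`` holds unordered (i, j) index pairs; ``kappa_group_a``
    applies to patients, ``kappa_group_b`` to controls.
    """

    band_center_hz: float
    region_pairs: tuple[tuple[int, int], ...]
    kappa_group_a: float
    kappa_group_b: float

    def __post_init__(self) -> None:
        for kappa in (self.kappa_group_a, self.kappa_group_b):
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
        if self.band_center_hz <= 0:
            raise ValueError("band_center_hz must be positive")
        norm = []
        seen = set()
        for i, j in self.region_pairs:
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            if a == b:
                raise ValueError(f"degenerate pair ({i}, {j})")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b})")
            seen.add((a, b))
            norm.append((a, b))
        object.__setattr__(self, "region_pairs", tuple(norm))

    def kappa_for_group(self, group: int) -> float:
        return self.kappa_group_a if group == PATIENT else self.kappa_group_b


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 20 patients vs 21 controls, 90
    regions, 27 epochs of 10 s sampled at 600 Hz, and a 30-point log
    frequency grid from 1 to 75 Hz. Tests and desk-scale runs override the
    counts downward; the generator semantics do not change with scale.
    """

    n_group_a: int = 20  # patients
    n_group_b: int = 21  # controls
    n_regions: int = 90
    n_epochs: int = 27
    epoch_duration_s: float = 10.0
    sampling_rate_hz: float = 600.0
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 1.0  # background amplitude relative to unit oscillations
    pink_noise_exponent: float = 1.0
    phase_jitter_sd: float = DEFAULT_PHASE_JITTER_SD
    phase_jitter_tau_s: float = DEFAULT_PHASE_JITTER_TAU_S
    kappa_subject_sd: float = 0.1  # between-subject spread of coupling
    score_coupling: float = 120.0  # severity units per unit kappa deviation
    score_noise_sd: float = 12.0
    severity_mean_patient: float = 20.0
    severity_mean_control: float = 2.0
    symptoms_mean_patient: float = 9.0
    symptoms_mean_control: float = 1.0
    symptoms_coupling: float = 40.0
    symptoms_noise_sd: float = 4.0
    days_coupling_r: float = -0.5  # target corr(days, alpha coupling)
    days_range: tuple[float, float] = (3.0, 90.0)
    n_frequencies: int = 30
    f_min_hz: float = 1.0
    f_max_hz: float = 75.0
    beta_concentration: float = 60.0  # tensor fast path: Beta(mu*nu, (1-mu)*nu)
    noise_floor_plv: float = 0.14  # finite-sample PLV floor emulated by the fast path
    seed: int = 0

    def __post_init__(self) -> None:
        self.effects = tuple(self.effects)
        for name in ("n_group_a", "n_group_b", "n_regions", "n_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_samp = self.epoch_duration_s * self.sampling_rate_hz
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_duration_s * sampling_rate_hz must be an integer")
        nyquist = self.sampling_rate_hz / 2.0
        for eff in self.effects:
            if eff.band_center_hz >= nyquist:
                raise ValueError(
                    f"effect frequency {eff.band_center_hz} Hz >= Nyquist {nyquist} Hz"
                )
            for i, j in eff.region_pairs:
                if j >= self.n_regions:
                    raise ValueError(
                        f"effect pair ({i}, {j}) references region >= {self.n_regions}"
                    )

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def n_samples_per_epoch(self) -> int:
        return int(round(self.epoch_duration_s * self.sampling_rate_hz))

    def frequency_grid(self) -> FrequencyGrid:
        return make_frequency_grid(self.n_frequencies, self.f_min_hz, self.f_max_hz)

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [
            {
                "band_center_hz": e.band_center_hz,
                "region_pairs": [list(p) for p in e.region_pairs],
                "kappa_group_a": e.kappa_group_a,
                "kappa_group_b": e.kappa_group_b,
            }
            for e in self.effects
        ]
        d["days_range"] = list(self.days_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["effects"] = tuple(
            EffectSpec(
                band_center_hz=e["band_center_hz"],
                region_pairs=tuple(tuple(p) for p in e["region_pairs"]),
                kappa_group_a=e["kappa_group_a"],
                kappa_group_b=e["kappa_group_b"],
            )
            for e in d.get("effects", ())
        )
        d["days_range"] = tuple(d.get("days_range", (3.0, 90.0)))
        return cls(**d)


@dataclass
class SourceTimeSeriesSet:
    """Per-subject epoched multi-region signals.

    ``data`` has shape (n_subjects, n_epochs, n_regions, n_samples).
    """

    data: np.ndarray
    sampling_rate_hz: float
    region_names: list[str]
    subject_ids: list[str]


# ---------------------------------------------------------------------------
# low-level generators


def _ou_process(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    alpha = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - alpha**2)
    drive = np.empty(n)
    drive[0] = rng.normal(0.0, sd)  # stationary start
    drive[1:] = rng.normal(0.0, innov_sd, size=n - 1)
    # x[k] = alpha*x[k-1] + drive[k] as an IIR filter
    return sp_signal.lfilter([1.0], [1.0, -alpha], drive)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    """Zero-mean 1/f**exponent noise of length ``n`` scaled to ``sd``."""
    white = rng.standard_normal(n)
    spec = sp_fft.rfft(white)
    freqs = sp_fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = sp_fft.irfft(spec * scale, n)
    shaped -= shaped.mean()
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


#: Constant-Q edge ratio of the driver band-pass (band = [f/Q, f*Q]).
_DRIVER_BAND_Q = 1.25


def _jittered_oscillation(
    rng: np.random.Generator,
    frequency_hz: float,
    n: int,
    dt: float,
    jitter_sd: float,
    jitter_tau: float,
) -> np.ndarray:
    """Unit-SD narrowband driver: phase-jittered cosine, band-pass confined.

    The OU phase jitter dephases the oscillation (setting the PLV noise
    floor) but also spreads energy into spectral sidebands; a zero-phase
    constant-Q Butterworth band-pass around the carrier removes the spread
    so planted couplings stay frequency-specific.
    """
    t = np.arange(n) * dt
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    eta = _ou_process(rng, n, dt, jitter_sd, jitter_tau)
    raw = np.cos(2.0 * np.pi * frequency_hz * t + theta0 + eta)
    fs = 1.0 / dt
    hi = min(frequency_hz * _DRIVER_BAND_Q, 0.48 * fs)
    sos = sp_signal.butter(
        2, [frequency_hz / _DRIVER_BAND_Q, hi], "bandpass", fs=fs, output="sos"
    )
    filtered = sp_signal.sosfiltfilt(sos, raw)
    sd = filtered.std()
    return filtered / sd if sd > 0 else filtered


def simulate_coupled_pair(
    frequency_hz: float,
    kappa: float,
    duration_s: float,
    sampling_rate_hz: float,
    seed: int | np.random.Generator,
    phase_jitter_sd: float = DEFAULT_PHASE_JITTER_SD,
    phase_jitter_tau_s: float = DEFAULT_PHASE_JITTER_TAU_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Two zero-mean oscillations sharing a stochastic driver with weight ``kappa``.

    Each output mixes the common driver (weight kappa) with its own
    independent driver (weight sqrt(1-kappa^2)); see the module docstring.
    At kappa = 1 the pair is phase-locked at a constant lag (PLV -> 1); at
    kappa = 0 the phases wander independently and the measured PLV drops to
    the finite-sample noise floor.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    if frequency_hz >= sampling_rate_hz / 2.0:
        raise ValueError(
            f"frequency {frequency_hz} Hz is at or above Nyquist "
            f"({sampling_rate_hz / 2.0} Hz)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    dt = 1.0 / sampling_rate_hz
    common = _jittered_oscillation(
        rng, frequency_hz, n, dt, phase_jitter_sd, phase_jitter_tau_s
    )
    own = _jittered_oscillation(
        rng, frequency_hz, n, dt, phase_jitter_sd, phase_jitter_tau_s
    )
    x = common - common.mean()
    y = kappa * common + np.sqrt(1.0 - kappa**2) * own
    return x, y - y.mean()


# ---------------------------------------------------------------------------
# cohort-level helpers


def _subject_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[tuple[int, int], np.ndarray]]:
    """Draw group labels, per-subject couplings and clinical covariates.

    Returns the subject table and a map {(effect_idx, subject_idx): kappa}
    realized per subject (group kappa plus between-subject jitter).
    """
    n = config.n_subjects
    groups = np.array([PATIENT] * config.n_group_a + [CONTROL] * config.n_group_b)
    subject_ids = [
        f"{'tbi' if g == PATIENT else 'ctl'}{i:03d}" for i, g in enumerate(groups)
    ]

    kappas: dict[tuple[int, int], np.ndarray] = {}
    for ei, eff in enumerate(config.effects):
        base = np.where(groups == PATIENT, eff.kappa_group_a, eff.kappa_group_b)
        jitter = rng.normal(0.0, config.kappa_subject_sd, size=n)
        kappas[ei] = np.clip(base + jitter, 0.0, 1.0)

    # realized alpha coupling deviation from the configured group mean
    alpha_idx = [
        ei for ei, eff in enumerate(config.effects) if band_of(eff.band_center_hz) == "alpha"
    ]
    if alpha_idx:
        realized = np.mean([kappas[ei] for ei in alpha_idx], axis=0)
        configured = np.mean(
            [
                np.where(
                    groups == PATIENT,
                    config.effects[ei].kappa_group_a,
                    config.effects[ei].kappa_group_b,
                )
                for ei in alpha_idx
            ],
            axis=0,
        )
        dev = realized - configured
    else:
        realized = np.zeros(n)
        dev = np.zeros(n)

    sev_base = np.where(
        groups == PATIENT, config.severity_mean_patient, config.severity_mean_control
    )
    severity = np.maximum(
        0.0,
        sev_base + config.score_coupling * dev + rng.normal(0.0, config.score_noise_sd, n),
    )
    sym_base = np.where(
        groups == PATIENT, config.symptoms_mean_patient, config.symptoms_mean_control
    )
    symptoms = np.maximum(
        0.0,
        sym_base + config.symptoms_coupling * dev + rng.normal(0.0, config.symptoms_noise_sd, n),
    )

    # days since injury: patients only, rank-remapped uniform support so the
    # Spearman/Pearson correlation with alpha coupling matches the target sign
    days = np.full(n, np.nan)
    patients = np.flatnonzero(groups == PATIENT)
    lo, hi = config.days_range
    raw_days = np.sort(rng.uniform(lo, hi, size=patients.size))
    z_k = dev[patients]
    sd = z_k.std()
    z_k = z_k / sd if sd > 0 else np.zeros_like(z_k)
    r = config.days_coupling_r
    latent = r * z_k + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(patients.size)
    days[patients] = raw_days[np.argsort(np.argsort(latent))]

    table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "severity": severity,
            "symptoms": symptoms,
            "days_since_injury": days,
            "alpha_coupling": realized,  # generator ground truth (extra column)
        }
    )
    return table, kappas


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SourceTimeSeriesSet, pd.DataFrame]:
    """Signal-level cohort: oscillations with planted pair couplings + 1/f noise.

    Every region receives pink background noise of SD ``noise_sd``; each
    planted pair additionally injects a unit-amplitude oscillation at the
    effect frequency into both of its regions, with the phase-coupling model
    described in the module docstring. Identical (config, seed) give
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    table, kappas = _subject_metadata(config, rng)
    n_samp = config.n_samples_per_epoch
    dt = 1.0 / config.sampling_rate_hz
    t = np.arange(n_samp) * dt
    data = np.zeros(
        (config.n_subjects, config.n_epochs, config.n_regions, n_samp), dtype=float
    )
    for s in range(config.n_subjects):
        for e in range(config.n_epochs):
            for ei, eff in enumerate(config.effects):
                kappa = float(kappas[ei][s])
                mix = np.sqrt(1.0 - kappa**2)
                for i, j in eff.region_pairs:
                    common = _jittered_oscillation(
                        rng, eff.band_center_hz, n_samp, dt,
                        config.phase_jitter_sd, config.phase_jitter_tau_s,
                    )
                    own = _jittered_oscillation(
                        rng, eff.band_center_hz, n_samp, dt,
                        config.phase_jitter_sd, config.phase_jitter_tau_s,
                    )
                    # drivers are unit SD, amplitude-matching the background
                    data[s, e, i] += common
                    data[s, e, j] += kappa * common + mix * own
            for r_idx in range(config.n_regions):
                data[s, e, r_idx] += _pink_noise(
                    rng, n_samp, config.pink_noise_exponent, config.noise_sd
                )
                data[s, e, r_idx] -= data[s, e, r_idx].mean()
    sts = SourceTimeSeriesSet(
        data=data,
        sampling_rate_hz=config.sampling_rate_hz,
        region_names=region_names(config.n_regions),
        subject_ids=list(table["subject_id"]),
    )
    return sts, table


def simulate_plv_tensor(
    config: SimulationConfig,
) -> tuple[ConnectivityTensor, pd.DataFrame]:
    """Fast path: draw the PLV tensor directly from Beta distributions.

    Cell means follow floor + (1 - floor) * expected_plv(kappa) on planted
    (frequency, pair) cells — the analytic coupling map lifted onto the
    configured finite-sample noise floor — and the floor elsewhere; the Beta
    concentration emulates epoch-averaging variance. Metadata contract
    identical to :func:`simulate_cohort`.
    """
    rng = np.random.default_rng(config.seed)
    table, kappas = _subject_metadata(config, rng)
    grid = config.frequency_grid()
    n_p = n_pairs(config.n_regions)
    floor = config.noise_floor_plv
    nu = config.beta_concentration
    mu = np.full((config.n_subjects, len(grid), n_p), floor)
    for ei, eff in enumerate(config.effects):
        fi = grid.nearest_index(eff.band_center_hz)
        cols = [pair_index(i, j, config.n_regions) for i, j in eff.region_pairs]
        for s in range(config.n_subjects):
            mu[s, fi, cols] = floor + (1.0 - floor) * expected_plv(float(kappas[ei][s]))
    mu = np.clip(mu, 1e-3, 1.0 - 1e-3)  # keep Beta parameters valid
    a = mu * nu
    b = (1.0 - mu) * nu
    values = rng.beta(a, b)
    tensor = ConnectivityTensor(
        plv=np.clip(values, 0.0, 1.0),
        frequencies_hz=grid.frequencies_hz,
        pairs=pair_list(config.n_regions),
        subject_ids=list(table["subject_id"]),
        region_names=region_names(config.n_regions),
    )
    return tensor, table
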