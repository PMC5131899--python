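"""End-to-end orchestration: simulate -> PLV -> classify -> PLS.

A single global seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``: stage i uses child i in
the fixed order (simulate, connectivity, classification, pls), so any stage
can be re-run in isolation with the same stream. Rerunning an identical
config reproduces every numeric artifact exactly; the run manifest records
the config hash, per-stage seeds, wall times and output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from megsync import __version__
from megsync.connectivity import (
    ConnectivityTensor,
    pair_list,
    subject_connectivity,
)
from megsync.classification import (
    accuracy_by_band,
    accuracy_vs_k,
    confidence_score_correlation,
    features_from_tensor,
    permutation_null,
)
from megsync.grid import FrequencyGrid, BAND_NAMES
from megsync.pls import (
    bootstrap_ratios,
    build_element_matrix,
    lv_permutation_test,
    tail_counts,
)
from megsync.synthetic import SimulationConfig, simulate_cohort, simulate_plv_tensor
from megsync import io as mio

STAGES = ("simulate", "connectivity", "classification", "pls")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed (< 2**31) from the global seed."""
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(global_seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tensor_only: bool = False  # fast path: skip signal synthesis
    n_cycles: float = 7.0
    classification_band: str = "alpha"
    k_max: int = 0  # 0 disables the k-curve
    svm_c: float = 1.0
    n_perm_classification: int = 0  # 0 disables the label-shuffle null
    pls_n_perm: int = 99
    pls_n_boot: int = 99
    tail_q: float = 0.01
    behaviour_column: str = "days_since_injury"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classification_band not in BAND_NAMES:
            raise ValueError(
                f"unknown band {self.classification_band!r}; expected one of {BAND_NAMES}"
            )
        if not 0.0 < self.tail_q < 0.5:
            raise ValueError("tail_q must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["simulation"] = SimulationConfig.from_dict(d.get("simulation", {}))
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stage_seeds: dict
    wall_time_s: dict
    file_digests: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full chain and write all artifacts plus a manifest.

    A stage failure raises with the stage name; artifacts written before
    the failure stay on disk next to a ``FAILED`` marker naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    times: dict[str, float] = {}
    sim = config.simulation
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim_seeded = SimulationConfig.from_dict({**sim.to_dict(), "seed": seeds["simulate"]})
        if config.tensor_only:
            tensor, table = simulate_plv_tensor(sim_seeded)
        else:
            sts, table = simulate_cohort(sim_seeded)
            mio.write_timeseries(out / "timeseries.h5", sts)
        mio.write_subject_table(out / "subjects.csv", table)
        times[stage] = time.perf_counter() - t0

        stage = "connectivity"
        t0 = time.perf_counter()
        grid = sim.frequency_grid()
        if not config.tensor_only:
            slabs = np.array(
                [
                    subject_connectivity(
                        sts.data[s], sim.sampling_rate_hz, grid, config.n_cycles
                    )
                    for s in range(sim.n_subjects)
                ]
            )
            tensor = ConnectivityTensor(
                plv=slabs,
                frequencies_hz=grid.frequencies_hz,
                pairs=pair_list(sim.n_regions),
                subject_ids=sts.subject_ids,
                region_names=sts.region_names,
            )
        mio.write_tensor(out / "tensor.h5", tensor)
        times[stage] = time.perf_counter() - t0

        stage = "classification"
        t0 = time.perf_counter()
        labels = table["group"].to_numpy()
        band_outcomes = accuracy_by_band(tensor, labels, c=config.svm_c)
        results: dict = {
            "band_accuracy": {
                b: {
                    "accuracy": o.accuracy,
                    "sensitivity": o.sensitivity,
                    "specificity": o.specificity,
                }
                for b, o in band_outcomes.items()
            }
        }
        band_fs = features_from_tensor(
            tensor, labels, FrequencyGrid(tensor.frequencies_hz).band_indices(config.classification_band)
        )
        if config.k_max:
            k_max = min(config.k_max, band_fs.n_features)
            outcomes, best_k = accuracy_vs_k(band_fs, k_max=k_max, c=config.svm_c)
            results["k_curve"] = {
                "k": list(range(1, k_max + 1)),
                "accuracy": [o.accuracy for o in outcomes],
                "best_k": best_k,
            }
            corr = confidence_score_correlation(
                outcomes, table["severity"].to_numpy(), labels
            )
            results["confidence_severity_r"] = {k: v[0] for k, (v) in corr.items()}
        if config.n_perm_classification:
            null = permutation_null(
                band_fs,
                k_best=None,
                c=config.svm_c,
                n_perm=config.n_perm_classification,
                seed=seeds["classification"],
                observed_accuracy=band_outcomes[config.classification_band].accuracy,
            )
            results["band_null_p"] = null.p_value
        mio.write_json(out / "classification.json", results)
        times[stage] = time.perf_counter() - t0

        stage = "pls"
        t0 = time.perf_counter()
        em = build_element_matrix(tensor, labels)
        rng = np.random.default_rng(seeds["pls"])
        p_contrast, model = lv_permutation_test(em, config.pls_n_perm, rng)
        ratios = bootstrap_ratios(em, config.pls_n_boot, rng)
        upper, lower, thr = tail_counts(ratios, em.n_frequencies, config.tail_q)
        pls_results = {
            "contrast": {
                "singular_values": model.singular_values,
                "lv_p_values": p_contrast,
                "tail_upper_counts": upper,
                "tail_lower_counts": lower,
                "tail_thresholds": thr,
            }
        }
        patients = table["group"] == 1
        behaviour = table.loc[patients, config.behaviour_column].to_numpy()
        if np.isfinite(behaviour).all() and np.std(behaviour) > 0:
            p_beh, beh_model = lv_permutation_test(
                em,
                config.pls_n_perm,
                rng,
                behaviour=behaviour,
                rows=em.group_slices[0],
            )
            beh_ratios = bootstrap_ratios(
                em, config.pls_n_boot, rng, behaviour=behaviour, rows=em.group_slices[0]
            )
            b_up, b_lo, b_thr = tail_counts(beh_ratios, em.n_frequencies, config.tail_q)
            pls_results["behavioural"] = {
                "singular_value": beh_model.singular_values,
                "overall_correlation": beh_model.overall_correlation,
                "lv_p_values": p_beh,
                "tail_upper_counts": b_up,
                "tail_lower_counts": b_lo,
                "tail_thresholds": b_thr,
            }
        mio.write_json(out / "pls.json", pls_results)
        times[stage] = time.perf_counter() - t0
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    digests = {
        p.name: _digest(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=__version__,
        stage_seeds=seeds,
        wall_time_s=times,
        file_digests=digests,
    )
    mio.write_json(out / "manifest.json", manifest.to_dict())
    return manifest
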