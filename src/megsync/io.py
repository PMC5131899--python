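"""File formats: HDF5 time series and tensors, CSV metadata, JSON results.

Schemas
-------
Time series HDF5: one group ``subjects/<id>`` per subject with dataset
``data`` (epochs x regions x samples); root attrs ``sampling_rate_hz`` and
dataset ``region_names``. Tensor HDF5: datasets ``plv`` (subjects x
frequencies x pairs), ``frequencies_hz``, ``pairs`` (n_pairs x 2),
``subject_ids``, ``region_names``. Subject tables are CSV with the header
``subject_id,group,severity,symptoms,days_since_injury`` (extra columns are
preserved). Write-then-read is the identity on all payload fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from megsync.connectivity import ConnectivityTensor
from megsync.synthetic import SourceTimeSeriesSet

SUBJECT_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "severity",
    "symptoms",
    "days_since_injury",
]


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


def write_timeseries(path: str | Path, sts: SourceTimeSeriesSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = sts.sampling_rate_hz
        f.create_dataset(
            "region_names", data=np.array(sts.region_names, dtype="S")
        )
        grp = f.create_group("subjects")
        for i, sid in enumerate(sts.subject_ids):
            grp.create_group(sid).create_dataset("data", data=sts.data[i])


def read_timeseries(path: str | Path) -> SourceTimeSeriesSet:
    with h5py.File(path, "r") as f:
        if "subjects" not in f or "sampling_rate_hz" not in f.attrs:
            raise SchemaError("time-series file missing 'subjects' group or rate attr")
        region_names = [n.decode() for n in f["region_names"][()]]
        ids = list(f["subjects"].keys())
        data = np.stack([f["subjects"][sid]["data"][()] for sid in ids])
        return SourceTimeSeriesSet(
            data=data,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            region_names=region_names,
            subject_ids=ids,
        )


def write_tensor(path: str | Path, tensor: ConnectivityTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("plv", data=tensor.plv)
        f.create_dataset("frequencies_hz", data=tensor.frequencies_hz)
        f.create_dataset("pairs", data=tensor.pairs)
        f.create_dataset("subject_ids", data=np.array(tensor.subject_ids, dtype="S"))
        f.create_dataset("region_names", data=np.array(tensor.region_names, dtype="S"))


def read_tensor(path: str | Path) -> ConnectivityTensor:
    with h5py.File(path, "r") as f:
        missing = {"plv", "frequencies_hz", "pairs", "subject_ids", "region_names"} - set(f)
        if missing:
            raise SchemaError(f"tensor file missing datasets: {sorted(missing)}")
        return ConnectivityTensor(
            plv=f["plv"][()],
            frequencies_hz=f["frequencies_hz"][()],
            pairs=f["pairs"][()],
            subject_ids=[s.decode() for s in f["subject_ids"][()]],
            region_names=[s.decode() for s in f["region_names"][()]],
        )


def write_subject_table(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in SUBJECT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"subject table missing columns: {missing}")
    table.to_csv(path, index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SUBJECT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"subject table missing columns: {missing}")
    if not set(table["group"].unique()) <= {1, -1}:
        raise SchemaError("group column must contain only +1 / -1")
    return table


def export_matrix_csv(
    path: str | Path, tensor: ConnectivityTensor, subject_idx: int, freq_idx: int
) -> None:
    """Single-frequency symmetric PLV matrix as region-labelled CSV."""
    mat = tensor.matrix(subject_idx, freq_idx)
    pd.DataFrame(mat, index=tensor.region_names, columns=tensor.region_names).to_csv(
        path
    )


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
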