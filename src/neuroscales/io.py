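"""Plain-text (TSV/YAML) and HDF5 readers and writers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_connectome_tsv",
    "read_connectome_tsv",
    "write_connectome_hdf5",
    "read_connectome_hdf5",
    "write_series_tsv",
    "read_series_tsv",
    "write_series_hdf5",
    "read_series_hdf5",
    "write_yaml",
    "read_yaml",
]


def write_matrix_tsv(path, matrix, header: list[str] | None = None) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=header)
    df.to_csv(path, sep="\t", index=False, header=header is not None)


def read_matrix_tsv(path, header: bool = True):
    df = pd.read_csv(path, sep="\t", header=0 if header else None)
    labels = list(df.columns) if header else None
    return df.to_numpy(dtype=float), labels


def write_connectome_tsv(path, connectome) -> None:
    """Square weight matrix with a one-line header of region labels."""
    write_matrix_tsv(path, connectome.weights, header=list(connectome.region_labels))


def read_connectome_tsv(path):
    from .synthetic import StructuralConnectome

    weights, labels = read_matrix_tsv(path, header=True)
    return StructuralConnectome(weights=weights, region_labels=labels)


def write_connectome_hdf5(path, connectome, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=connectome.weights)
        f.create_dataset(
            "region_labels",
            data=np.array(connectome.region_labels, dtype=h5py.string_dtype()),
        )
        if provenance:
            for key, value in provenance.items():
                f.attrs[key] = value


def read_connectome_hdf5(path):
    from .synthetic import StructuralConnectome

    with h5py.File(path, "r") as f:
        weights = f["weights"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["region_labels"][()]]
    return StructuralConnectome(weights=weights, region_labels=labels)


def write_series_tsv(path, series, sidecar: dict | None = None) -> None:
    """Region x time matrix as TSV plus an optional YAML sidecar (same stem)."""
    arr = np.asarray(getattr(series, "bold", series))
    pd.DataFrame(arr).to_csv(path, sep="\t", index=False, header=False)
    if sidecar is not None:
        write_yaml(Path(path).with_suffix(".yaml"), sidecar)


def read_series_tsv(path):
    arr = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    sidecar_path = Path(path).with_suffix(".yaml")
    sidecar = read_yaml(sidecar_path) if sidecar_path.exists() else None
    return arr, sidecar


def write_series_hdf5(path, series, params=None) -> None:
    """Neuronal time series (rates + gating) with dt, seed and parameters."""
    with h5py.File(path, "w") as f:
        for name in ("r_E", "r_I", "S_E", "S_I"):
            f.create_dataset(name, data=getattr(series, name), compression="gzip")
        f.attrs["dt"] = series.dt
        f.attrs["duration"] = series.duration
        f.attrs["seed"] = series.seed
        if series.integration_dt is not None:
            f.attrs["integration_dt"] = series.integration_dt
        if params is not None:
            for key, value in params.__dict__.items():
                f.attrs[f"param_{key}"] = value


def read_series_hdf5(path):
    from .dmf import NeuronalTimeSeries

    with h5py.File(path, "r") as f:
        series = NeuronalTimeSeries(
            r_E=f["r_E"][()], r_I=f["r_I"][()],
            S_E=f["S_E"][()], S_I=f["S_I"][()],
            dt=float(f.attrs["dt"]), duration=float(f.attrs["duration"]),
            seed=int(f.attrs["seed"]),
            integration_dt=float(f.attrs.get("integration_dt", f.attrs["dt"])),
        )
        params = {k[len("param_"):]: f.attrs[k] for k in f.attrs if k.startswith("param_")}
    return series, params


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_yaml(path, payload: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_to_plain(payload), f, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
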