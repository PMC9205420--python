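"""File I/O and reproducible configuration-driven runs.

HDF5 is the canonical container for arrays (time series: groups ``/data``,
``/fs``, ``/labels``; models: ``/A``, ``/order``, ...); CSV serves
matrices and tables so results stay readable across languages. Labels, not
indices, are the join key between structural matrices and time-series
channels; purely positional joining is accepted only when both sides are
unlabeled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datamodel import StructuralPrior, TimeSeriesData, TVMVARModel

logger = logging.getLogger("sistok")

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_sc",
    "write_sc",
    "write_model",
    "read_model",
    "write_mdi",
    "run_config",
]


def write_timeseries(path: str | Path, data: TimeSeriesData) -> None:
    """Write a time series to HDF5 (/data, /fs, /labels)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=data.values)
        h5.create_dataset("fs", data=float(data.sampling_rate))
        if data.channel_labels is not None:
            h5.create_dataset(
                "labels", data=np.array(data.channel_labels, dtype=h5py.string_dtype())
            )
        if data.time_axis is not None:
            h5.create_dataset("time", data=data.time_axis)


def _read_h5_timeseries(path: Path) -> TimeSeriesData:
    with h5py.File(path, "r") as h5:
        if "data" not in h5:
            raise ValueError(f"{path}: missing /data group")
        values = np.asarray(h5["data"])
        if "fs" not in h5:
            raise ValueError(f"{path}: missing sampling rate (/fs)")
        fs = float(h5["fs"][()])
        labels = None
        if "labels" in h5:
            labels = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["labels"][()]]
        time_axis = np.asarray(h5["time"]) if "time" in h5 else None
    return TimeSeriesData(values, fs, labels, time_axis)


def _read_csv_dir(path: Path, sampling_rate: float | None) -> TimeSeriesData:
    files = sorted(path.glob("*.csv"))
    if not files:
        raise ValueError(f"{path}: no trial CSV files found")
    if sampling_rate is None:
        fs_file = path / "sampling_rate.txt"
        if not fs_file.exists():
            raise ValueError(
                f"{path}: missing sampling rate (pass sampling_rate= or add sampling_rate.txt)"
            )
        sampling_rate = float(fs_file.read_text().strip())
    frames = []
    labels: list[str] | None = None
    for fp in files:
        df = pd.read_csv(fp)
        if not all(np.issubdtype(t, np.number) for t in df.dtypes):
            raise ValueError(f"{fp}: non-numeric cells in trial file")
        cols = [str(c) for c in df.columns]
        if labels is None:
            labels = cols
        elif cols != labels:
            raise ValueError(f"{fp}: channel headers differ from {files[0].name}")
        frames.append(df.to_numpy(dtype=float).T)  # (channels, samples)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"{path}: trial shapes differ across files: {sorted(shapes)}")
    return TimeSeriesData(np.stack(frames), sampling_rate, labels)


def read_timeseries(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
) -> TimeSeriesData:
    """Read a multi-trial time series.

    ``format`` is ``"hdf5"`` or ``"csv_dir"`` (a directory with one CSV per
    trial, channels as columns); inferred from the path when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv_dir" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return _read_h5_timeseries(path)
    if format == "csv_dir":
        return _read_csv_dir(path, sampling_rate)
    raise ValueError(f"unknown format {format!r}")


def write_sc(path: str | Path, prior: StructuralPrior) -> None:
    labels = prior.labels or [str(i) for i in range(prior.n_nodes)]
    pd.DataFrame(prior.W, index=labels, columns=labels).to_csv(path)


def read_sc(path: str | Path) -> StructuralPrior:
    """Read a structural-connectivity matrix from a labeled CSV.

    Rows are receivers, columns are senders; row and column label sets must
    be identical (and in the same order). Negative entries are rejected.
    The normalization state (max == 1) is detected and recorded.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: SC matrix is not square ({df.shape[0]}x{df.shape[1]})")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels and column labels differ")
    W = df.to_numpy(dtype=float)
    if np.any(W < 0):
        raise ValueError(f"{path}: SC matrix contains negative entries")
    normalized = bool(np.isclose(W.max(), 1.0))
    diag = W[np.diag_indices_from(W)]
    diagonal_value = float(diag[0]) if np.allclose(diag, diag[0]) else None
    prior = StructuralPrior(W=W, normalized=normalized, diagonal_value=diagonal_value, labels=rows)
    logger.info("read SC %s: %d nodes, normalized=%s", path, prior.n_nodes, normalized)
    return prior


def write_model(path: str | Path, model: TVMVARModel) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("A", data=model.A)
        h5.create_dataset("order", data=model.order)
        h5.create_dataset("variance_fraction", data=model.variance_fraction)
        h5.create_dataset("c_trace", data=model.c_trace)
        h5.create_dataset("innovations", data=model.innovations)
        h5.create_dataset("valid_from", data=model.valid_from)
        if model.channel_labels is not None:
            h5.create_dataset(
                "labels", data=np.array(model.channel_labels, dtype=h5py.string_dtype())
            )
        h5.attrs["metadata"] = json.dumps(model.metadata)


def read_model(path: str | Path) -> TVMVARModel:
    with h5py.File(path, "r") as h5:
        labels = None
        if "labels" in h5:
            labels = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["labels"][()]]
        return TVMVARModel(
            A=np.asarray(h5["A"]),
            order=int(h5["order"][()]),
            variance_fraction=float(h5["variance_fraction"][()]),
            c_trace=np.asarray(h5["c_trace"]),
            innovations=np.asarray(h5["innovations"]),
            valid_from=int(h5["valid_from"][()]),
            channel_labels=labels,
            metadata=json.loads(h5.attrs.get("metadata", "{}")),
        )


def write_mdi(path: str | Path, tensor) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("mdi", data=tensor.values)
        h5.create_dataset("valid_from", data=tensor.valid_from)
        h5.attrs["mode"] = tensor.mode
        if tensor.labels is not None:
            h5.create_dataset(
                "labels", data=np.array(tensor.labels, dtype=h5py.string_dtype())
            )


_CONFIG_KEYS = {
    "seed": None,
    "out_dir": None,
    "simulate": {"nodes", "order", "samples", "trials", "onset", "offset",
                 "driver", "coupling", "scenario"},
    "fit": {"filter", "order", "variance_fraction", "sc", "sc_min", "sc_max",
            "c_mode", "c_fixed", "input"},
    "mdi": {"mode"},
}


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in _CONFIG_KEYS.items():
        if allowed is None or key not in cfg:
            continue
        extra = set(cfg[key]) - allowed
        if extra:
            raise ValueError(f"unknown keys in '{key}' section: {sorted(extra)}")


def run_config(path: str | Path) -> dict:
    """Execute a simulate -> fit -> mdi pipeline from a YAML config.

    Unknown keys are rejected (no silent defaults for misspellings). Every
    run writes a provenance record (config hash, package version, seed)
    next to its outputs and returns a dict of produced paths.
    """
    from . import __version__
    from .metrics import mdi as compute_mdi
    from .priors import si_stok_fit
    from .simulate import evoked_spec, generate_sc_scenarios, simulate_tvmvar
    from .stok import stok_fit

    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) or {}
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", path.parent / "sistok_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}

    sim = cfg.get("simulate", {})
    spec, edges = evoked_spec(
        d=int(sim.get("nodes", 5)),
        p=int(sim.get("order", 2)),
        n_samples=int(sim.get("samples", 200)),
        n_trials=int(sim.get("trials", 40)),
        onset=int(sim.get("onset", 80)),
        offset=int(sim.get("offset", 160)),
        driver=int(sim.get("driver", 0)),
        coupling=float(sim.get("coupling", 0.35)),
        seed=seed,
    )
    logger.info("simulate: d=%d p=%d N=%d trials=%d", spec.d, spec.p,
                spec.n_samples, spec.n_trials)
    data, _ = simulate_tvmvar(spec)
    data_path = out_dir / "sim.h5"
    write_timeseries(data_path, data)
    produced["data"] = str(data_path)

    scenario = sim.get("scenario", "concordant")
    prior = generate_sc_scenarios(edges, scenario, spec.d)
    sc_path = out_dir / "sim_sc.csv"
    write_sc(sc_path, prior)
    produced["sc"] = str(sc_path)

    fit_cfg = cfg.get("fit", {})
    p = int(fit_cfg.get("order", spec.p))
    f = float(fit_cfg.get("variance_fraction", 0.99))
    c_mode = fit_cfg.get("c_mode", "adaptive")
    c_fixed = fit_cfg.get("c_fixed")
    flavor = fit_cfg.get("filter", "si_stok")
    logger.info("fit: filter=%s order=%d f=%.3g", flavor, p, f)
    if flavor == "stok":
        model = stok_fit(data, p, f, c_mode=c_mode, c_fixed=c_fixed)
    elif flavor == "si_stok":
        sc_source = fit_cfg.get("sc", "simulated")
        fit_prior = prior if sc_source == "simulated" else read_sc(sc_source)
        model = si_stok_fit(
            data, p, f, prior=fit_prior,
            scaling=(float(fit_cfg.get("sc_min", 1e-4)), float(fit_cfg.get("sc_max", 0.1))),
            c_mode=c_mode, c_fixed=c_fixed,
        )
    else:
        raise ValueError(f"unknown filter {flavor!r} in fit section")
    model_path = out_dir / "model.h5"
    write_model(model_path, model)
    produced["model"] = str(model_path)

    tensor = compute_mdi(model, mode=cfg.get("mdi", {}).get("mode", "rss"))
    mdi_path = out_dir / "mdi.h5"
    write_mdi(mdi_path, tensor)
    produced["mdi"] = str(mdi_path)

    provenance = {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "package_version": __version__,
        "seed": seed,
        "outputs": produced,
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2))
    produced["provenance"] = str(prov_path)
    logger.info("run complete: %s", out_dir)
    return produced
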