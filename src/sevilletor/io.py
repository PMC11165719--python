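"""Record serialization: config.yaml + per-snapshot CSV matrices.

A :class:`~sevilletor.lattice.SimulationRecord` is written as a directory
containing ``config.yaml`` (full provenance: scheme, seed, parameters,
config hash) and one CSV matrix per field per snapshot, named
``u_t{time:08.2f}.csv``.  Values are printed with 17 significant digits so
that the round trip is bit-exact for IEEE doubles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .lattice import NumericalScheme, SimulationRecord

__all__ = ["save_record", "load_record", "write_summary"]


def _write_matrix(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, arr, delimiter=",", fmt="%.17g")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_record(record: SimulationRecord, outdir: str | Path, png: bool = False) -> Path:
    """Serialize a record to a directory; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": record.config,
        "scheme": dataclasses.asdict(record.scheme),
        "seed": record.seed,
        "times": [float(t) for t in record.times],
        "diverged": record.diverged,
        "config_hash": record.config_hash,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    for t, u, v, m in zip(record.times, record.u_snapshots, record.v_snapshots, record.masks):
        _write_matrix(out / f"u_t{t:08.2f}.csv", u)
        _write_matrix(out / f"v_t{t:08.2f}.csv", v)
        _write_matrix(out / f"mask_t{t:08.2f}.csv", m.astype(int))
    if png:  # pragma: no cover - cosmetic output
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for t, v in zip(record.times, record.v_snapshots):
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(v.T, cmap="RdBu", origin="lower")
            ax.set_title(f"v at t={t:.2f}")
            fig.savefig(out / f"v_t{t:08.2f}.png", dpi=80)
            plt.close(fig)
    return out


def load_record(indir: str | Path) -> SimulationRecord:
    """Load a record saved by :func:`save_record`."""
    src = Path(indir)
    with open(src / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    times = [float(t) for t in meta["times"]]
    u_snaps, v_snaps, masks = [], [], []
    for t in times:
        u_snaps.append(_read_matrix(src / f"u_t{t:08.2f}.csv"))
        v_snaps.append(_read_matrix(src / f"v_t{t:08.2f}.csv"))
        masks.append(_read_matrix(src / f"mask_t{t:08.2f}.csv").astype(bool))
    return SimulationRecord(
        times=times,
        u_snapshots=u_snaps,
        v_snapshots=v_snaps,
        scheme=NumericalScheme(**meta["scheme"]),
        seed=meta["seed"],
        config=meta["config"],
        masks=masks,
        diverged=meta["diverged"],
    )


def write_summary(path: str | Path, record: SimulationRecord, **extra) -> None:
    """Write a run summary (classification, wave stats, provenance) as JSON."""
    payload = {
        "config_hash": record.config_hash,
        "seed": record.seed,
        "final_time": record.times[-1],
        "diverged": record.diverged,
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
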