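"""Plain-text serialisation: JSON-lines trajectories and run manifests."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np

from .fssh import HopEvent, SimParams, Trajectory

__all__ = ["load_trajectories_jsonl", "save_trajectories_jsonl", "write_manifest"]


def _traj_record(tr: Trajectory) -> dict:
    return {
        "times": tr.times.tolist(),
        "active_state": tr.active_state.tolist(),
        "store_stride": tr.store_stride,
        "coeff_re": np.real(tr.quantum_coeffs).tolist(),
        "coeff_im": np.imag(tr.quantum_coeffs).tolist(),
        "R": tr.R.tolist(),
        "P": tr.P.tolist(),
        "hops": [vars(h) for h in tr.hops],
        "band_entry_times": tr.band_entry_times,
        "initial_state": tr.initial_state,
        "band_map": {str(k): v for k, v in tr.band_map.items()},
        "params": vars(tr.params),
    }


def save_trajectories_jsonl(trajectories, path, compress: bool | None = None) -> None:
    path = Path(path)
    if compress is None:
        compress = path.suffix == ".gz"
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for tr in trajectories:
            fh.write(json.dumps(_traj_record(tr)) + "\n")


def load_trajectories_jsonl(path) -> list[Trajectory]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            d = json.loads(line)
            coeffs = np.array(d["coeff_re"]) + 1j * np.array(d["coeff_im"])
            out.append(
                Trajectory(
                    times=np.array(d["times"]),
                    active_state=np.array(d["active_state"], dtype=np.int16),
                    quantum_coeffs=coeffs,
                    R=np.array(d["R"]),
                    P=np.array(d["P"]),
                    store_stride=d["store_stride"],
                    hops=[HopEvent(**h) for h in d["hops"]],
                    band_entry_times=d["band_entry_times"],
                    params=SimParams(**d["params"]),
                    initial_state=d["initial_state"],
                    band_map={int(k): v for k, v in d["band_map"].items()},
                )
            )
    return out


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
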