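"""Space-time activity fields.

A :class:`SpaceTimeField` stores the activity ``e_j^n`` of a lattice run on a
grid of (step, layer-slot, channel).  Layer slot 0 corresponds to the layer
index ``j_offset``; all layer indexing helpers go through that offset so that
runs on truncated infinite domains keep their absolute layer labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CSV_HEADER = ["n", "j", "channel", "value"]


@dataclass
class SpaceTimeField:
    """Activity over (step n | time t, layer j, channel).

    Parameters
    ----------
    values
        Array of shape ``(T, J, d)``.  ``d`` is 1 for scalar runs.
    j_offset
        Layer index of slot 0.
    domain
        ``"infinite_truncated"`` or ``"semi_infinite"``.
    times
        Optional physical sample times (ms) for continuous-time runs; when
        absent the first axis is the integer step counter.
    """

    values: np.ndarray
    j_offset: int = 0
    domain: str = "infinite_truncated"
    times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must have shape (T, J, d)")
        if self.domain not in ("infinite_truncated", "semi_infinite"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.values.shape[0],):
                raise ValueError("times must match the first axis of values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_steps(self) -> int:
        return self.values.shape[0] - 1

    @property
    def n_layers(self) -> int:
        return self.values.shape[1]

    @property
    def channel_dim(self) -> int:
        return self.values.shape[2]

    @property
    def layers(self) -> np.ndarray:
        """Absolute layer indices for each slot."""
        return np.arange(self.n_layers) + self.j_offset

    def slot(self, j: int) -> int:
        s = j - self.j_offset
        if not 0 <= s < self.n_layers:
            raise IndexError(f"layer {j} outside stored range "
                             f"[{self.j_offset}, {self.j_offset + self.n_layers - 1}]")
        return s

    def at(self, n: int, j: int, channel: int = 0) -> float:
        """Value at step ``n`` and absolute layer index ``j``."""
        return float(self.values[n, self.slot(j), channel])

    def profile(self, n: int, channel: int = 0) -> np.ndarray:
        return self.values[n, :, channel]

    @property
    def scalar(self) -> np.ndarray:
        """The (T, J) view of a single-channel field."""
        if self.channel_dim != 1:
            raise ValueError("field has more than one channel")
        return self.values[:, :, 0]

    def layer_sum(self, channel: int = 0) -> np.ndarray:
        """Sum over layers at each step (mass of the field)."""
        return self.values[:, :, channel].sum(axis=1)

    def select_channel(self, channel: int) -> "SpaceTimeField":
        return replace(self, values=self.values[:, :, channel:channel + 1],
                       meta=dict(self.meta))

    # -- truncation certificate -----------------------------------------
    def edge_magnitude(self) -> float:
        """Largest absolute value on the truncation edges, relative to the
        overall scale of the field.  Small values certify that the truncated
        domain behaved like the infinite one."""
        scale = max(1.0, float(np.max(np.abs(self.values))))
        if self.domain == "semi_infinite":
            edge = np.abs(self.values[:, -1, :])
        else:
            edge = np.abs(self.values[:, [0, -1], :])
        return float(np.max(edge)) / scale


class FieldFormatError(ValueError):
    """Raised when a persisted field cannot be parsed back."""


def save_field(f: SpaceTimeField, path: str | Path, format: str = "archive") -> Path:
    """Persist a field as a columnar CSV table or a binary array archive.

    The archive round trip is bit exact; the CSV format keeps 17 significant
    digits which is enough to reproduce IEEE doubles.
    """
    path = Path(path)
    meta = {
        "j_offset": int(f.j_offset),
        "domain": f.domain,
        "channel_dim": int(f.channel_dim),
        "extra": f.meta,
    }
    if format == "archive":
        kwargs = {"values": f.values, "j_offset": np.int64(f.j_offset),
                  "meta": np.array(json.dumps(meta))}
        if f.times is not None:
            kwargs["times"] = f.times
        np.savez(path, **kwargs)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        return path
    if format == "csv":
        T, J, d = f.values.shape
        n_idx = np.repeat(np.arange(T), J * d)
        j_idx = np.tile(np.repeat(f.layers, d), T)
        c_idx = np.tile(np.arange(d), T * J)
        df = pd.DataFrame({"n": n_idx, "j": j_idx, "channel": c_idx,
                           "value": f.values.ravel()})
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            if f.times is not None:
                fh.write("# times=" + json.dumps(f.times.tolist()) + "\n")
            df.to_csv(fh, index=False, float_format="%.17g")
        return path
    raise ValueError(f"unknown format {format!r}")


def load_field(path: str | Path) -> SpaceTimeField:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            try:
                meta = json.loads(str(data["meta"]))
                values = data["values"]
            except KeyError as exc:
                raise FieldFormatError(f"archive {path} missing entry {exc}") from exc
            times = data["times"] if "times" in data else None
        return SpaceTimeField(values, j_offset=meta["j_offset"], domain=meta["domain"],
                              times=times, meta=meta.get("extra", {}))
    # CSV path
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise FieldFormatError(f"{path}:1: expected '# ' metadata line")
        meta = json.loads(first[2:])
        pos = fh.tell()
        second = fh.readline()
        times = None
        if second.startswith("# times="):
            times = np.array(json.loads(second[len("# times="):]))
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != CSV_HEADER:
        raise FieldFormatError(f"{path}: header must be {','.join(CSV_HEADER)}")
    T = int(df["n"].max()) + 1
    d = meta["channel_dim"]
    j0 = meta["j_offset"]
    J = int(df["j"].max()) - j0 + 1
    if len(df) != T * J * d:
        raise FieldFormatError(
            f"{path}: expected {T * J * d} rows for a (T={T}, J={J}, d={d}) "
            f"field, found {len(df)} (truncated or padded file)")
    values = np.asarray(df["value"]).reshape(T, J, d)
    return SpaceTimeField(values, j_offset=j0, domain=meta["domain"], times=times,
                          meta=meta.get("extra", {}))


def fields_equal(a: SpaceTimeField, b: SpaceTimeField, atol: float = 0.0) -> bool:
    if a.values.shape != b.values.shape or a.j_offset != b.j_offset:
        return False
    if a.domain != b.domain:
        return False
    if atol == 0.0:
        return bool(np.array_equal(a.values, b.values))
    return bool(np.allclose(a.values, b.values, atol=atol, rtol=0))
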