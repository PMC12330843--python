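"""Build, normalize, store, and load the (T2, B1+) echo-curve dictionary.

The dictionary holds one Bloch-simulated echo-modulation curve per (T2, B1+)
node, simulated at a single fixed T1 (1.5 s by default: at 7 T the T1
influence on the echo modulation is weak for T1 >> T2).  Rows are
L2-normalized across the echo dimension; the pre-normalization norms
``rho_theta`` are kept so the matcher can recover the signal amplitude S0.

Row ordering is T2-major, B1-minor: ``index = i_t2 * n_b1 + i_b1``.
Storage is a single HDF5 container with datasets /curves (float32),
/t2_ms, /b1_fraction, /rho_theta (float64), and a JSON attribute block
carrying the protocol, simulator settings, and a fingerprint hash.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .bloch import _propagate_ensemble
from .sequence import MESEProtocol, build_mese_timeline, protocol_fingerprint


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulator settings that shape the dictionary (part of its fingerprint)."""

    mode: str = "shaped"  # "shaped" or "ideal"
    n_rf_steps: int = 256
    ideal_crusher_cycles: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ParameterGrid:
    """Sorted, deduplicated (T2, B1) lattice with a fixed T1."""

    t2_ms: np.ndarray
    b1_fraction: np.ndarray
    t1_ms: float = 1500.0

    def __post_init__(self) -> None:
        for name, v in (("t2_ms", self.t2_ms), ("b1_fraction", self.b1_fraction)):
            v = np.asarray(v, dtype=float)
            if v.size == 0:
                raise GridError(f"{name} is empty")
            if np.any(v <= 0):
                raise GridError(f"{name} must be positive")
            if np.any(np.diff(v) <= 0):
                raise GridError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)
        if self.t1_ms <= 0:
            raise GridError("t1_ms must be positive")

    @property
    def size(self) -> int:
        return self.t2_ms.size * self.b1_fraction.size


#: T2 segments of the default production grid (ms): fine below 60 ms where
#: cortical/subcortical values live, coarser toward CSF-like values.
DEFAULT_T2_SEGMENTS = ((1.0, 60.0, 0.25), (60.0, 120.0, 2.0), (120.0, 600.0, 10.0))
DEFAULT_B1_RANGE = (0.2, 1.6, 0.01)


def _lattice(start: float, stop: float, step: float) -> np.ndarray:
    if step <= 0 or stop < start:
        raise GridError(f"invalid segment ({start}, {stop}, {step})")
    n = int(round((stop - start) / step))
    vals = start + step * np.arange(n + 1)
    return vals[vals <= stop + 1e-9]


def make_grid(
    t2_segments=DEFAULT_T2_SEGMENTS,
    b1_range=DEFAULT_B1_RANGE,
    t1_ms: float = 1500.0,
) -> ParameterGrid:
    """Union of inclusive-endpoint T2 segment lattices plus a uniform B1 range.

    Shared segment endpoints are deduplicated (round to 1e-6 ms).
    """
    if not t2_segments:
        raise GridError("at least one T2 segment is required")
    pieces = [_lattice(*seg) for seg in t2_segments]
    t2 = np.unique(np.round(np.concatenate(pieces), 6))
    b1 = np.unique(np.round(_lattice(*b1_range), 6))
    return ParameterGrid(t2, b1, t1_ms)


@dataclass(frozen=True)
class Dictionary:
    """L2-normalized simulated echo curves over the parameter grid."""

    grid: ParameterGrid
    curves: np.ndarray       # (N, etl), unit L2 rows
    rho_theta: np.ndarray    # (N,) pre-normalization norms
    fingerprint: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.curves.shape[0] != self.grid.size:
            raise ValueError("curve count does not match grid size")
        if np.any(self.rho_theta <= 0):
            raise ValueError("rho_theta must be positive")

    @property
    def etl(self) -> int:
        return self.curves.shape[1]

    @property
    def n_entries(self) -> int:
        return self.curves.shape[0]

    def entry_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-row (t2_ms, b1_fraction), in row order (T2-major)."""
        t2 = np.repeat(self.grid.t2_ms, self.grid.b1_fraction.size)
        b1 = np.tile(self.grid.b1_fraction, self.grid.t2_ms.size)
        return t2, b1

    def row_index(self, t2_ms: float, b1: float) -> int:
        i = int(np.argmin(np.abs(self.grid.t2_ms - t2_ms)))
        j = int(np.argmin(np.abs(self.grid.b1_fraction - b1)))
        return i * self.grid.b1_fraction.size + j


def build_dictionary(grid: ParameterGrid, protocol: MESEProtocol,
                     sim: SimConfig | None = None) -> Dictionary:
    """Simulate and L2-normalize the dictionary over the grid.

    Vectorizes over T2 (relaxation enters per-interval as a diagonal scale)
    and loops over B1 values, which change the RF rotations.
    """
    sim = sim or SimConfig()
    timeline = build_mese_timeline(protocol, mode=sim.mode, n_rf_steps=sim.n_rf_steps,
                                   ideal_crusher_cycles=sim.ideal_crusher_cycles)
    z = protocol.isochromat_positions()
    r1 = np.full(grid.t2_ms.size, 1.0 / grid.t1_ms)  # 1/ms
    r2 = 1.0 / grid.t2_ms
    n_b1 = grid.b1_fraction.size
    curves = np.empty((grid.t2_ms.size, n_b1, protocol.etl))
    for j, b1 in enumerate(grid.b1_fraction):
        try:
            curves[:, j, :] = _propagate_ensemble(timeline, r1, r2, float(b1), z)
        except Exception as err:
            raise RuntimeError(f"simulation failed at B1 = {b1:g}") from err
    flat = curves.reshape(grid.size, protocol.etl)
    rho = np.linalg.norm(flat, axis=1)
    if np.any(rho <= 0):
        bad = np.argwhere(rho <= 0)[0, 0]
        t2s, b1s = np.unravel_index(bad, (grid.t2_ms.size, n_b1))
        raise RuntimeError(
            f"zero-signal dictionary entry at T2 = {grid.t2_ms[t2s]:g} ms, "
            f"B1 = {grid.b1_fraction[b1s]:g}"
        )
    fp = protocol_fingerprint(protocol, sim.to_dict())
    meta = {
        "protocol": protocol.to_dict(),
        "sim": sim.to_dict(),
        "version": __version__,
        "row_order": "t2_major",
    }
    return Dictionary(grid, flat / rho[:, None], rho, fp, meta)


def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("curves", data=dictionary.curves.astype(np.float32))
        f.create_dataset("t2_ms", data=dictionary.grid.t2_ms.astype(np.float64))
        f.create_dataset("b1_fraction", data=dictionary.grid.b1_fraction.astype(np.float64))
        f.create_dataset("rho_theta", data=dictionary.rho_theta.astype(np.float64))
        f.attrs["t1_ms"] = dictionary.grid.t1_ms
        f.attrs["fingerprint"] = dictionary.fingerprint
        f.attrs["meta"] = json.dumps(dictionary.meta, default=float)


def load_dictionary(path: str | Path,
                    protocol: MESEProtocol | None = None,
                    sim: SimConfig | None = None) -> Dictionary:
    """Load an HDF5 dictionary; verify the fingerprint when a protocol is given."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            grid = ParameterGrid(f["t2_ms"][()], f["b1_fraction"][()],
                                 float(f.attrs["t1_ms"]))
            d = Dictionary(grid, f["curves"][()].astype(np.float64),
                           f["rho_theta"][()], str(f.attrs["fingerprint"]),
                           json.loads(f.attrs["meta"]))
    except OSError as err:
        raise IOError(f"cannot read dictionary container {path}") from err
    if protocol is not None:
        expected = protocol_fingerprint(protocol, (sim or SimConfig()).to_dict())
        if expected != d.fingerprint:
            warnings.warn(
                f"dictionary fingerprint {d.fingerprint} does not match the "
                f"supplied protocol ({expected}); curves may not describe this sequence",
                stacklevel=2,
            )
    return d
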