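"""Bloch propagation of isochromat ensembles through a MESE timeline.

The magnetization state per isochromat is the augmented 4-vector
``(Mx, My, Mz, M0)``; the fourth component carries the equilibrium
magnetization and is invariant under propagation.  Each timeline interval is
applied as a rotation about the effective field followed by relaxation over
the interval duration (rotate-then-relax operator splitting; the EPG test
oracle uses the same convention).  The echo-train signal is the magnitude of
the complex sum of transverse components over the ensemble, normalized by
the isochromat count.

Only slice gradients enter the effective field; B0 inhomogeneity, diffusion,
eddy currents, and in-plane gradients are out of model scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import GAMMA_KHZ_PER_MT, Interval, MESEProtocol, SequenceTimeline

TWO_PI = 2.0 * np.pi


class PropagationError(RuntimeError):
    """Non-finite magnetization encountered during propagation."""


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of a (single-compartment) sample.

    ``t2_ms`` may exceed ``t1_ms``: dictionary grids deliberately cover
    physically implausible corners.
    """

    t1_ms: float = 1500.0
    t2_ms: float = 80.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")

    @property
    def r1(self) -> float:  # 1/ms
        return 1.0 / self.t1_ms

    @property
    def r2(self) -> float:  # 1/ms
        return 1.0 / self.t2_ms


@dataclass(frozen=True)
class EchoTrainSignal:
    """Echo magnitudes at the echo times of the train."""

    echo_times_ms: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.echo_times_ms) != len(self.magnitudes):
            raise ValueError("echo_times and magnitudes length mismatch")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")


def _rotation_matrices(wx, wy, wz, dt):
    """Rodrigues rotation matrices for effective fields, broadcast over inputs.

    ``wx, wy, wz`` are rotation rates (rad/ms); the rotation angle over the
    interval is |w| * dt about the axis w/|w|.  Returns (..., 3, 3).
    """
    wx, wy, wz = np.broadcast_arrays(wx, wy, wz)
    omega = np.sqrt(wx * wx + wy * wy + wz * wz)
    theta = omega * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(omega > 0, wx / omega, 0.0)
        ny = np.where(omega > 0, wy / omega, 0.0)
        nz = np.where(omega > 0, wz / omega, 1.0)
    c, s = np.cos(theta), np.sin(theta)
    one_c = 1.0 - c
    R = np.empty(theta.shape + (3, 3))
    R[..., 0, 0] = c + nx * nx * one_c
    R[..., 0, 1] = nx * ny * one_c - nz * s
    R[..., 0, 2] = nx * nz * one_c + ny * s
    R[..., 1, 0] = ny * nx * one_c + nz * s
    R[..., 1, 1] = c + ny * ny * one_c
    R[..., 1, 2] = ny * nz * one_c - nx * s
    R[..., 2, 0] = nz * nx * one_c - ny * s
    R[..., 2, 1] = nz * ny * one_c + nx * s
    R[..., 2, 2] = c + nz * nz * one_c
    return R


def _axis_rotation(flip_rad: float, phase_rad: float) -> np.ndarray:
    """Rotation by flip_rad about the transverse axis at azimuth phase_rad."""
    return _rotation_matrices(
        np.cos(phase_rad) * flip_rad, np.sin(phase_rad) * flip_rad, 0.0, 1.0
    )


def propagator(dt: float, rf_amplitude: float, rf_phase: float, gz: float,
               z_mm: float, tissue: TissueParams) -> np.ndarray:
    """4x4 linear map for one hard-pulse interval at isochromat position z.

    Composition (rotate-then-relax): rotation about the effective field
    (RF at ``rf_phase`` plus gradient off-resonance gamma*Gz*z), then
    transverse decay exp(-dt*R2) and longitudinal recovery toward M0 through
    the augmented fourth component.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    wz = TWO_PI * GAMMA_KHZ_PER_MT * gz * z_mm * 1e-3  # rad/ms
    wx = rf_amplitude * np.cos(rf_phase)
    wy = rf_amplitude * np.sin(rf_phase)
    R3 = _rotation_matrices(wx, wy, wz, dt)
    e2 = np.exp(-dt * tissue.r2)
    e1 = np.exp(-dt * tissue.r1)
    relax = np.diag([e2, e2, e1, 1.0])
    relax[2, 3] = 1.0 - e1
    P = np.eye(4)
    P[:3, :3] = R3
    return relax @ P


def _propagate_ensemble(timeline: SequenceTimeline, r1, r2, b1_scale: float,
                        z_mm: np.ndarray) -> np.ndarray:
    """Run the timeline for P parameter sets sharing one B1 scale.

    ``r1``/``r2`` are arrays of shape (P,) in 1/ms; ``z_mm`` the isochromat
    positions (n,).  Returns echo magnitudes of shape (P, etl), already
    normalized by the isochromat count.
    """
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    n = z_mm.size
    P = r1.size
    M = np.zeros((P, n, 3))
    M[:, :, 2] = 1.0  # equilibrium (0, 0, 1, 1): M0 handled analytically
    idx = np.arange(n)

    echoes = np.empty((P, timeline.n_echoes))
    i_echo = 0
    for i_iv, iv in enumerate(timeline.intervals):
        if iv.kind == "echo":
            sig = np.abs(M[:, :, 0].sum(axis=1) + 1j * M[:, :, 1].sum(axis=1)) / n
            echoes[:, i_echo] = sig
            i_echo += 1
            continue
        if iv.kind == "pulse":
            R = _axis_rotation(iv.flip_rad * b1_scale, iv.phase)
            M = M @ R.T
        elif iv.kind == "crusher":
            phi = TWO_PI * iv.cycles * idx / n
            c, s = np.cos(phi), np.sin(phi)
            mx = M[:, :, 0] * c - M[:, :, 1] * s
            my = M[:, :, 0] * s + M[:, :, 1] * c
            M[:, :, 0], M[:, :, 1] = mx, my
        elif iv.kind in ("delay", "rf"):
            if iv.kind == "rf" or iv.gz != 0.0:
                wz = TWO_PI * GAMMA_KHZ_PER_MT * iv.gz * z_mm * 1e-3
                if iv.kind == "rf":
                    w1 = iv.omega1 * b1_scale
                    R = _rotation_matrices(w1 * np.cos(iv.phase),
                                           w1 * np.sin(iv.phase), wz, iv.dt)
                    M = np.einsum("nij,pnj->pni", R, M)
                else:
                    phi = wz * iv.dt
                    c, s = np.cos(phi), np.sin(phi)
                    mx = M[:, :, 0] * c - M[:, :, 1] * s
                    my = M[:, :, 0] * s + M[:, :, 1] * c
                    M[:, :, 0], M[:, :, 1] = mx, my
            if iv.dt > 0:
                e2 = np.exp(-iv.dt * r2)[:, None]
                e1 = np.exp(-iv.dt * r1)[:, None]
                M[:, :, 0] *= e2
                M[:, :, 1] *= e2
                M[:, :, 2] = M[:, :, 2] * e1 + (1.0 - e1)
        else:  # pragma: no cover
            raise ValueError(f"unknown interval kind {iv.kind!r}")
        if not np.all(np.isfinite(M)):
            raise PropagationError(f"non-finite magnetization at interval {i_iv}")
    return echoes


def simulate_echo_train(timeline: SequenceTimeline, tissue: TissueParams,
                        b1_scale: float = 1.0,
                        z_mm: np.ndarray | None = None) -> EchoTrainSignal:
    """Simulate one echo-modulation curve.

    Parameters
    ----------
    timeline : SequenceTimeline
        From :func:`emct2.sequence.build_mese_timeline`.
    tissue : TissueParams
    b1_scale : float
        Transmit-field scale (fraction of nominal); scales every RF rotation.
    z_mm : ndarray, optional
        Isochromat positions.  Required for shaped timelines; in ideal mode a
        default uniform grid is used (positions only matter through crushers,
        which are position-free index dephasers there).
    """
    if b1_scale <= 0:
        raise ValueError("b1_scale must be positive")
    if z_mm is None:
        if timeline.mode == "shaped":
            raise ValueError("shaped timelines need explicit isochromat positions")
        z_mm = np.linspace(-5.0, 5.0, 64)
    z_mm = np.asarray(z_mm, dtype=float)
    if z_mm.size == 0:
        raise ValueError("isochromat grid must be non-empty")
    mags = _propagate_ensemble(timeline, tissue.r1, tissue.r2, b1_scale, z_mm)[0]
    return EchoTrainSignal(timeline.echo_times_ms.copy(), mags * tissue.m0)
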