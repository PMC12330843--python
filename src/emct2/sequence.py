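"""Multi-echo spin-echo (MESE) protocol description and sequence timeline.

The timeline is the bridge between a scanner-level protocol (echo spacing,
flip angles, pulse shapes, spoilers) and the Bloch propagation engine: it is
an ordered list of piecewise-constant intervals (hard-pulse approximation)
with slice-gradient amplitudes, plus instantaneous-event entries used by the
idealized mode (hard pulses, exact crusher dephasing) that the test oracles
rely on.

Conventions
-----------
* Internal times are milliseconds, rates 1/ms, gradients mT/m.
* t = 0 at the excitation pulse center; echo k is centered at k * esp and
  refocusing pulse k at (k - 1/2) * esp (CPMG timing).
* CPMG phase convention: excitation about x, refocusing about y.
* The excitation slice-rephase area is folded into the first spoiler lobe
  (both are z-gradients); this keeps the default 9 ms echo spacing feasible
  and leaves the primary spin-echo pathway fully rephased at each echo.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

GAMMA_KHZ_PER_MT = 42.577
"""Gyromagnetic ratio of 1H, kHz/mT (= MHz/T)."""


class TimingError(ValueError):
    """A requested interval layout does not fit inside the echo spacing."""


@dataclass(frozen=True)
class RFPulse:
    """Named RF pulse shape with duration and time-bandwidth product."""

    shape: Literal["hann_sinc", "hard"] = "hann_sinc"
    duration_ms: float = 2.56
    time_bandwidth: float = 2.7

    def envelope(self, n_steps: int) -> np.ndarray:
        """Unit-integral amplitude envelope sampled at ``n_steps`` midpoints."""
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.shape == "hard":
            env = np.ones(n_steps)
        elif self.shape == "hann_sinc":
            # symmetric support [-1/2, 1/2] of the pulse duration
            t = (np.arange(n_steps) + 0.5) / n_steps - 0.5
            env = np.sinc(self.time_bandwidth * t) * (0.5 + 0.5 * np.cos(2 * np.pi * t))
        else:  # pragma: no cover - guarded by the Literal type
            raise ValueError(f"unknown RF shape {self.shape!r}")
        return env / env.sum()

    @property
    def bandwidth_khz(self) -> float:
        return self.time_bandwidth / self.duration_ms


@dataclass(frozen=True)
class MESEProtocol:
    """2D multi-echo spin-echo protocol.

    Defaults reproduce the 7 T protocol this package targets: 9 ms echo
    spacing, 7 echoes, 90deg excitation with 140deg refocusing to limit SAR,
    0.7 mm slice simulated with 1000 isochromats over a 10 mm slab, and
    1.35 ms spoiler lobes of ~55 mT.ms/m straddling each refocusing pulse.
    """

    echo_spacing_ms: float = 9.0
    etl: int = 7
    excitation_flip_deg: float = 90.0
    refocusing_flip_deg: float = 140.0
    excitation_phase_deg: float = 0.0
    refocusing_phase_deg: float = 90.0
    slice_thickness_mm: float = 0.7
    slab_extent_mm: float = 10.0
    n_isochromats: int = 1000
    excitation_pulse: RFPulse = field(default_factory=lambda: RFPulse("hann_sinc", 2.56, 2.7))
    refocusing_pulse: RFPulse = field(default_factory=lambda: RFPulse("hann_sinc", 3.0, 2.7))
    spoiler_moment: float = 55.0  # mT.ms/m per lobe
    spoiler_duration_ms: float = 1.35
    tr_ms: float = 4500.0  # metadata only; finite-TR saturation is not simulated

    def __post_init__(self) -> None:
        if self.etl < 1:
            raise ValueError("etl must be >= 1")
        if self.echo_spacing_ms <= 0:
            raise ValueError("echo_spacing_ms must be positive")
        if self.slab_extent_mm < self.slice_thickness_mm:
            raise ValueError("slab_extent_mm must cover slice_thickness_mm")
        if self.n_isochromats < 2:
            raise ValueError("n_isochromats must be >= 2")
        if not 0.0 < self.refocusing_flip_deg < 360.0:
            raise ValueError("refocusing_flip_deg must lie in (0, 360)")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """TE_k = k * esp for k = 1..etl."""
        return self.echo_spacing_ms * np.arange(1, self.etl + 1, dtype=float)

    def slice_gradient(self, pulse: RFPulse) -> float:
        """Slice-select amplitude (mT/m) so the pulse bandwidth spans the slice."""
        return pulse.bandwidth_khz / (GAMMA_KHZ_PER_MT * self.slice_thickness_mm * 1e-3)

    def isochromat_positions(self) -> np.ndarray:
        """Cell-centered positions (mm) across the slab, symmetric about 0."""
        n = self.n_isochromats
        return (np.arange(n) + 0.5) / n * self.slab_extent_mm - self.slab_extent_mm / 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MESEProtocol":
        d = dict(d)
        for key in ("excitation_pulse", "refocusing_pulse"):
            if key in d and isinstance(d[key], dict):
                d[key] = RFPulse(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "MESEProtocol":
        """Load from a YAML or JSON protocol file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass(frozen=True)
class AFIProtocol:
    """Actual flip-angle imaging protocol: interleaved TR1 << TR2, one flip."""

    tr1_ms: float = 16.0
    tr2_ms: float = 160.0
    nominal_flip_deg: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tr1_ms < self.tr2_ms:
            raise ValueError("need tr2 > tr1 > 0")
        if not 0.0 < self.nominal_flip_deg < 180.0:
            raise ValueError("nominal_flip_deg must lie in (0, 180)")

    @property
    def nu(self) -> float:
        return self.tr2_ms / self.tr1_ms


# ---------------------------------------------------------------------------
# timeline


@dataclass(frozen=True)
class Interval:
    """One piecewise-constant (or instantaneous) element of the sequence.

    kind:
      "delay"   free evolution for dt with optional slice gradient gz
      "rf"      hard-pulse step: constant RF (omega1 rad/ms at nominal B1,
                phase rad) plus gradient gz for dt
      "pulse"   instantaneous rotation by flip_rad (scaled by B1) about phase
      "crusher" instantaneous ideal dephaser: isochromat i gets z-phase
                2*pi*cycles*i/N (exactly full cycles across the ensemble)
      "echo"    zero-duration readout marker at an echo center
    """

    kind: str
    dt: float = 0.0
    omega1: float = 0.0
    phase: float = 0.0
    gz: float = 0.0
    flip_rad: float = 0.0
    cycles: int = 0


@dataclass(frozen=True)
class SequenceTimeline:
    intervals: tuple[Interval, ...]
    echo_times_ms: np.ndarray
    mode: str  # "shaped" or "ideal"
    n_rf_steps: int

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def duration_ms(self) -> float:
        return float(sum(iv.dt for iv in self.intervals))


def _rf_steps(pulse: RFPulse, flip_deg: float, phase_deg: float, gz: float, n_steps: int) -> list[Interval]:
    """Discretize a shaped pulse into hard-pulse intervals totalling flip_deg."""
    env = pulse.envelope(n_steps)
    dt = pulse.duration_ms / n_steps
    flip = math.radians(flip_deg)
    # omega1 * dt summed over steps must equal the flip angle
    amps = env * flip / dt
    phase = math.radians(phase_deg)
    return [Interval("rf", dt=dt, omega1=a, phase=phase, gz=gz) for a in amps]


def build_mese_timeline(
    protocol: MESEProtocol,
    mode: Literal["shaped", "ideal"] = "shaped",
    n_rf_steps: int = 256,
    ideal_crusher_cycles: int = 1,
) -> SequenceTimeline:
    """Lay out the MESE sequence as propagation intervals.

    Shaped mode discretizes the configured RF shapes into ``n_rf_steps``
    hard-pulse segments under their slice-select gradients, with spoiler
    lobes straddling each refocusing pulse.  Ideal mode uses instantaneous
    pulses without slice selection and exact-cycle crushers; it reduces to
    the textbook CPMG picture and is what the EPG oracle reproduces.

    Raises
    ------
    TimingError
        If pulses plus spoilers cannot fit inside the echo spacing.
    """
    esp = protocol.echo_spacing_ms
    intervals: list[Interval] = []

    if mode == "ideal":
        intervals.append(
            Interval("pulse", flip_rad=math.radians(protocol.excitation_flip_deg),
                     phase=math.radians(protocol.excitation_phase_deg))
        )
        refocus = Interval("pulse", flip_rad=math.radians(protocol.refocusing_flip_deg),
                           phase=math.radians(protocol.refocusing_phase_deg))
        crush = Interval("crusher", cycles=ideal_crusher_cycles)
        half = Interval("delay", dt=esp / 2)
        for _ in range(protocol.etl):
            intervals += [half, crush, refocus, crush, half, Interval("echo")]
        return SequenceTimeline(tuple(intervals), protocol.echo_times_ms, "ideal", 0)

    if mode != "shaped":
        raise ValueError(f"unknown timeline mode {mode!r}")

    exc, ref = protocol.excitation_pulse, protocol.refocusing_pulse
    tsp = protocol.spoiler_duration_ms
    g_exc = protocol.slice_gradient(exc)
    g_ref = protocol.slice_gradient(ref)
    g_spoil = protocol.spoiler_moment / tsp

    # excitation center -> first refocusing center spans esp/2
    d1 = esp / 2 - exc.duration_ms / 2 - tsp - ref.duration_ms / 2
    if d1 < 0:
        raise TimingError(
            f"excitation-to-refocusing gap infeasible: half excitation "
            f"({exc.duration_ms / 2:g} ms) + spoiler ({tsp:g} ms) + half refocusing "
            f"({ref.duration_ms / 2:g} ms) exceed esp/2 = {esp / 2:g} ms"
        )
    # refocusing center -> echo center spans esp/2 (and echo -> next refocusing)
    d2 = esp / 2 - ref.duration_ms / 2 - tsp
    if d2 < 0:
        raise TimingError(
            f"refocusing-to-echo gap infeasible: half refocusing "
            f"({ref.duration_ms / 2:g} ms) + spoiler ({tsp:g} ms) exceed "
            f"esp/2 = {esp / 2:g} ms"
        )

    intervals += _rf_steps(exc, protocol.excitation_flip_deg,
                           protocol.excitation_phase_deg, g_exc, n_rf_steps)
    # fold the excitation slice-rephase area (second half of the select lobe)
    # into the first spoiler so the primary pathway is rephased at the echoes
    rephase_area = g_exc * exc.duration_ms / 2
    first_spoiler_g = (protocol.spoiler_moment - rephase_area) / tsp

    refocus_steps = _rf_steps(ref, protocol.refocusing_flip_deg,
                              protocol.refocusing_phase_deg, g_ref, n_rf_steps)
    for k in range(protocol.etl):
        pre_g = first_spoiler_g if k == 0 else g_spoil
        pre_delay = d1 if k == 0 else d2
        intervals.append(Interval("delay", dt=pre_delay))
        intervals.append(Interval("delay", dt=tsp, gz=pre_g))
        intervals += refocus_steps
        intervals.append(Interval("delay", dt=tsp, gz=g_spoil))
        intervals.append(Interval("delay", dt=d2))
        intervals.append(Interval("echo"))

    return SequenceTimeline(tuple(intervals), protocol.echo_times_ms, "shaped", n_rf_steps)


def protocol_fingerprint(protocol: MESEProtocol, sim_settings: dict | None = None) -> str:
    """Stable hash of the protocol plus simulator settings (dictionary provenance)."""
    payload = {"protocol": protocol.to_dict(), "sim": sim_settings or {}}
    blob = json.dumps(payload, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
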