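"""Extended-phase-graph (EPG) oracle for CPMG echo trains.

Independent reference for the Bloch ensemble simulator in the idealized
regime (instantaneous pulses, full crusher dephasing between pulses).  Uses
the classic (F+, F-*, Z) configuration-state algebra: RF mixing matrix,
unit dephasing shifts before and after each refocusing pulse, relaxation
only during the free-evolution halves (matching the simulator's
rotate-then-relax convention, which is exact for instantaneous pulses).

Excitation is 90deg about x, refocusing about y (CPMG).  The echo amplitude
is |F_0| at each echo center.
"""

from __future__ import annotations

import numpy as np


def epg_cpmg(flip_deg: float, esp_ms: float, etl: int, t2_ms: float,
             t1_ms: float, excitation_flip_deg: float = 90.0) -> np.ndarray:
    """Echo amplitudes (relative to M0) of an ideal-crusher CPMG train."""
    K = 2 * etl + 3  # highest reachable dephasing order, with margin
    Fp = np.zeros(K, dtype=complex)
    Fm = np.zeros(K, dtype=complex)   # Fm[k] = conj(F_{-k})
    Z = np.zeros(K, dtype=complex)
    Z[0] = 1.0

    def rf(alpha: float, phi: float) -> None:
        nonlocal Fp, Fm, Z
        c2, s2 = np.cos(alpha / 2) ** 2, np.sin(alpha / 2) ** 2
        sa, ca = np.sin(alpha), np.cos(alpha)
        e1, e2 = np.exp(1j * phi), np.exp(2j * phi)
        Fp, Fm, Z = (
            c2 * Fp + s2 * e2 * Fm - 1j * e1 * sa * Z,
            s2 / e2 * Fp + c2 * Fm + 1j / e1 * sa * Z,
            -0.5j / e1 * sa * Fp + 0.5j * e1 * sa * Fm + ca * Z,
        )

    def relax(dt: float) -> None:
        nonlocal Fp, Fm, Z
        e2, e1 = np.exp(-dt / t2_ms), np.exp(-dt / t1_ms)
        Fp *= e2
        Fm *= e2
        Z *= e1
        Z[0] += 1.0 - e1

    def shift() -> None:
        nonlocal Fp, Fm
        Fp = np.roll(Fp, 1)
        Fm = np.roll(Fm, -1)
        Fm[-1] = 0.0
        Fp[0] = np.conj(Fm[0])

    rf(np.radians(excitation_flip_deg), 0.0)  # excitation about x
    alpha = np.radians(flip_deg)
    echoes = np.empty(etl)
    for k in range(etl):
        relax(esp_ms / 2)
        shift()
        rf(alpha, np.pi / 2)  # refocusing about y
        shift()
        relax(esp_ms / 2)
        echoes[k] = abs(Fp[0])
    return echoes
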