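"""AFI transmit-field mapping with error propagation and B1 regularizer fusion.

Actual flip-angle imaging (AFI) acquires two steady-state images S1, S2 at
interleaved repetition times TR1 << TR2.  With nu = TR2/TR1 and r = S2/S1
the achieved flip angle follows from

    B1+ = (100 / alpha_set) * arccos((r nu - 1) / (nu - r))   [percent]

First-order propagation of the image noise (sigma1, sigma2) through r and
the exact derivative of the arccos expression yields sigma_B1 and the
relative-error map zeta = sigma_B1 / B1+.  Correlations between S1 and S2
and the error in nu are neglected.  zeta grows where B1+ is low (r -> 1),
which is exactly where AFI underestimates the field, so the regularizer
B1_REG is a zeta-weighted blend of the AFI map with the (smoothed)
dictionary-matching estimate B1_EMC:

    eta(zeta) = 1 - min(zeta / zeta_th, 1)
    B1_REG = eta * B1_AFI + (1 - eta) * B1_EMC

All B1 volumes here are in percent of nominal; zeta is a dimensionless
fraction (0.1 = 10% relative error), matching the empirical default
threshold zeta_th = 0.125.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sequence import AFIProtocol

#: Empirical default confidence threshold for the AFI relative error (fraction).
DEFAULT_ZETA_TH = 0.125


@dataclass
class B1Maps:
    """Co-registered transmit-field products (percent of nominal)."""

    b1_afi: np.ndarray
    zeta: np.ndarray
    b1_emc: np.ndarray | None = None
    b1_reg: np.ndarray | None = None
    valid: np.ndarray | None = None  # arccos-domain validity


def afi_b1_map(s1: np.ndarray, s2: np.ndarray, protocol: AFIProtocol):
    """B1+ in percent of nominal, plus the arccos-domain validity mask.

    Out-of-domain ratios (|argument| > 1) are clamped and masked invalid.
    """
    nu = protocol.nu
    if nu <= 1:
        raise ValueError("AFI protocol requires TR2 > TR1 (nu > 1)")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("S1/S2 shape mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), np.nan)
        u = (r * nu - 1.0) / (nu - r)
    valid = np.isfinite(u) & (np.abs(u) <= 1.0) & (s1 > 0)
    alpha = np.arccos(np.clip(u, -1.0, 1.0))
    b1 = 100.0 * np.degrees(alpha) / protocol.nominal_flip_deg
    b1 = np.where(np.isfinite(u), b1, np.nan)
    return b1, valid


def afi_ratio(b1_fraction, protocol: AFIProtocol):
    """Forward model: the ideal-spoiling AFI ratio r for a given B1 fraction."""
    alpha = np.radians(protocol.nominal_flip_deg) * np.asarray(b1_fraction, float)
    nu = protocol.nu
    return (1.0 + nu * np.cos(alpha)) / (nu + np.cos(alpha))


def afi_error_map(s1, s2, sigma1, sigma2, protocol: AFIProtocol):
    """Relative error map zeta = sigma_B1 / B1 (dimensionless fraction).

    sigma_r = (sigma1 * S2 + sigma2 * S1) / S1^2, and sigma_B1 uses the exact
    analytic derivative dB1/dr of the arccos signal equation.  Voxels outside
    the arccos domain (or with B1 = 0) get zeta = +inf: maximal distrust.
    """
    if sigma1 is None or sigma2 is None:
        raise ValueError("noise scales sigma1/sigma2 are required")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    nu = protocol.nu
    alpha_set_rad = math.radians(protocol.nominal_flip_deg)
    b1, valid = afi_b1_map(s1, s2, protocol)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s2 / s1
        u = (r * nu - 1.0) / (nu - r)
        sigma_r = (np.asarray(sigma1, float) * s2 + np.asarray(sigma2, float) * s1) / s1**2
        db1_dr = (100.0 / alpha_set_rad) * (nu**2 - 1.0) / ((nu - r) ** 2 * np.sqrt(1.0 - u**2))
        sigma_b1 = np.abs(db1_dr) * sigma_r
        zeta = sigma_b1 / b1
    zeta = np.where(valid & (b1 > 0) & np.isfinite(zeta), zeta, np.inf)
    return zeta


def eta_weight(zeta, zeta_th: float = DEFAULT_ZETA_TH):
    """Linear confidence weight of the AFI estimate: 1 at zeta=0, 0 beyond zeta_th."""
    if zeta_th <= 0:
        raise ValueError("zeta_th must be positive")
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0):
        raise ValueError("zeta must be non-negative")
    return 1.0 - np.minimum(zeta / zeta_th, 1.0)


def combine_b1(b1_afi, b1_emc, zeta, zeta_th: float = DEFAULT_ZETA_TH):
    """Convex per-voxel blend eta*B1_AFI + (1-eta)*B1_EMC (same-grid volumes)."""
    b1_afi = np.asarray(b1_afi, dtype=float)
    b1_emc = np.asarray(b1_emc, dtype=float)
    if b1_afi.shape != b1_emc.shape:
        raise ValueError("B1 map shape mismatch")
    eta = eta_weight(zeta, zeta_th)
    out = eta * b1_afi + (1.0 - eta) * b1_emc
    # where one input is undefined, fall back to the other
    out = np.where(np.isnan(b1_afi), b1_emc, out)
    out = np.where(np.isnan(b1_emc), b1_afi, out)
    return out


def smooth_emc_b1(b1_emc: np.ndarray, sigma_voxels: float = 5.0) -> np.ndarray:
    """Gaussian smoothing of the dictionary-derived B1 map (slowly varying field)."""
    if sigma_voxels == 0:
        return np.asarray(b1_emc, dtype=float).copy()
    vol = np.asarray(b1_emc, dtype=float)
    nan = np.isnan(vol)
    if nan.any():
        # normalized convolution so NaNs neither spread nor bias the field
        filled = np.where(nan, 0.0, vol)
        w = ndimage.gaussian_filter((~nan).astype(float), sigma_voxels, mode="nearest")
        sm = ndimage.gaussian_filter(filled, sigma_voxels, mode="nearest")
        with np.errstate(invalid="ignore"):
            out = sm / w
        out[nan & (w <= 1e-12)] = np.nan
        return out
    return ndimage.gaussian_filter(vol, sigma_voxels, mode="nearest")
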