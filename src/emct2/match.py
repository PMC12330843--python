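"""Voxel-wise dictionary grid search with optional B1+ regularization.

Each voxel's echo train is L2-normalized (keeping its norm rho_S) and
matched against the normalized dictionary rows by minimizing

    || s_hat - theta_hat ||_2  +  lambda * | B1_REG - B1_row |

where the penalty acts on the per-voxel scalar B1 expressed as a fraction of
nominal.  With no regularizer (lambda = 0, "pure EMC mode") the search is
the plain normalized-L2 match and its B1 argmin is the EMC transmit-field
estimate.  The amplitude estimate is S0 = rho_S / rho_theta at the winning
row.  Since every row has unit norm, the residual reduces to
sqrt(2 - 2 s_hat . theta_hat), so matching is a single matrix product per
voxel batch.

Excluded voxels (SNR below threshold, or all-zero trains) carry NaN in every
output map plus an explicit exclusion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .b1map import B1Maps, combine_b1, smooth_emc_b1
from .dictionary import Dictionary
from .noise import SNRMap


@dataclass(frozen=True)
class MatchConfig:
    """Matching options.

    lam is the Eq.-style regularization weight applied to the B1 *fraction*
    difference (a penalty of 0.01 per percent of B1 deviation at lam = 1).
    """

    lam: float = 1.0
    snr_threshold: float = 5.0
    batch_size: int = 4096
    zeta_th: float = 0.125
    b1_smooth_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class MapSet:
    """Fitted parameter maps; excluded voxels are NaN plus masked."""

    r2: np.ndarray          # 1/s
    t2: np.ndarray          # ms
    b1: np.ndarray          # percent of nominal
    s0: np.ndarray          # arbitrary units
    residual: np.ndarray    # normalized-L2 misfit term
    total_cost: np.ndarray  # residual + lam * |B1_REG - B1|
    excluded: np.ndarray    # bool
    snr: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def normalize_signal(curve: np.ndarray):
    """L2-normalize an echo train; returns (unit_curve, rho_S).

    All-zero curves cannot be normalized: rho_S = 0 signals exclusion.
    """
    curve = np.asarray(curve, dtype=float)
    rho = float(np.linalg.norm(curve))
    if rho == 0:
        return np.zeros_like(curve), 0.0
    return curve / rho, rho


def match_curves(curves: np.ndarray, dictionary: Dictionary,
                 b1_reg_fraction: np.ndarray | None = None,
                 lam: float = 0.0, batch_size: int = 4096):
    """Grid-search a batch of echo trains against the dictionary.

    Parameters
    ----------
    curves : ndarray (N, etl)
        Raw (un-normalized) magnitude trains.
    b1_reg_fraction : ndarray (N,), optional
        Per-curve B1 regularizer as a fraction of nominal; None disables the
        penalty regardless of lam.

    Returns
    -------
    dict with idx, t2_ms, b1_fraction, s0, residual, total_cost, valid.
    Ties in total cost resolve to the smaller T2, then (when a regularizer is
    present) the B1 value nearest to it.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be 2D (N, etl)")
    if curves.shape[1] != dictionary.etl:
        raise ValueError(
            f"echo count {curves.shape[1]} does not match dictionary etl {dictionary.etl}")
    N = curves.shape[0]
    t2_rows, b1_rows = dictionary.entry_params()
    theta = dictionary.curves  # (D, etl), unit rows

    rho = np.linalg.norm(curves, axis=1)
    valid = rho > 0
    unit = np.zeros_like(curves)
    unit[valid] = curves[valid] / rho[valid, None]

    idx = np.zeros(N, dtype=np.int64)
    resid = np.full(N, np.nan)
    cost = np.full(N, np.nan)
    use_reg = b1_reg_fraction is not None and lam > 0
    if b1_reg_fraction is not None:
        b1_reg_fraction = np.asarray(b1_reg_fraction, dtype=float)
        if b1_reg_fraction.shape != (N,):
            raise ValueError("b1_reg_fraction must have one value per curve")

    for lo in range(0, N, batch_size):
        hi = min(lo + batch_size, N)
        sel = slice(lo, hi)
        dots = unit[sel] @ theta.T
        res = np.sqrt(np.maximum(2.0 - 2.0 * dots, 0.0))
        if use_reg:
            pen = lam * np.abs(b1_reg_fraction[sel, None] - b1_rows[None, :])
            total = res + pen
        else:
            total = res
        best = np.argmin(total, axis=1)  # first minimum: smallest T2, then B1
        if use_reg:
            # break exact cost ties toward the B1 grid value nearest the regularizer
            rows = np.arange(hi - lo)
            tmin = total[rows, best]
            ties = np.isclose(total, tmin[:, None], rtol=0.0, atol=0.0)
            multi = np.where(ties.sum(axis=1) > 1)[0]
            for i in multi:
                cand = np.where(ties[i])[0]
                order = np.lexsort((np.abs(b1_rows[cand] - b1_reg_fraction[lo + i]),
                                    t2_rows[cand]))
                best[i] = cand[order[0]]
        idx[sel] = best
        rows = np.arange(hi - lo)
        resid[sel] = res[rows, best]
        cost[sel] = total[rows, best]

    out = {
        "idx": idx,
        "t2_ms": t2_rows[idx],
        "b1_fraction": b1_rows[idx],
        "s0": np.where(valid, rho / dictionary.rho_theta[idx], np.nan),
        "residual": resid,
        "total_cost": cost,
        "valid": valid,
    }
    for key in ("t2_ms", "b1_fraction", "residual", "total_cost"):
        out[key] = np.where(valid, out[key], np.nan)
    return out


def match_voxels(stack: np.ndarray, dictionary: Dictionary,
                 b1_reg: np.ndarray | None = None,
                 config: MatchConfig | None = None,
                 snr: SNRMap | None = None) -> MapSet:
    """Fit every voxel of a 4D echo stack.

    Parameters
    ----------
    stack : ndarray (X, Y, Z, E)
        Magnitude echo trains (ideally denoised and bias-corrected).
    b1_reg : ndarray (X, Y, Z), optional
        Regularizing B1 map in percent of nominal; absent -> lambda treated
        as zero (pure EMC mode).
    snr : SNRMap, optional
        Voxels with SNR strictly below ``config.snr_threshold`` are excluded
        up front.
    """
    config = config or MatchConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("need a 4D (X, Y, Z, E) stack")
    spatial = stack.shape[:3]
    flat = stack.reshape(-1, stack.shape[3])

    include = np.ones(spatial, dtype=bool)
    if snr is not None:
        include &= snr.snr >= config.snr_threshold
    inc = include.ravel()

    reg_flat = None
    lam = config.lam
    if b1_reg is not None:
        if b1_reg.shape != spatial:
            raise ValueError("b1_reg shape does not match the stack")
        reg_flat = (np.asarray(b1_reg, dtype=float).ravel() / 100.0)[inc]
    else:
        lam = 0.0

    res = match_curves(flat[inc], dictionary, reg_flat, lam, config.batch_size)

    def scatter(values, fill=np.nan):
        out = np.full(inc.shape, fill, dtype=float)
        out[inc] = values
        return out.reshape(spatial)

    t2 = scatter(res["t2_ms"])
    with np.errstate(invalid="ignore"):
        r2 = 1000.0 / t2
    excluded = ~(include & scatter(res["valid"], fill=0.0).astype(bool))
    for vol in (t2, r2):
        vol[excluded] = np.nan
    mapset = MapSet(
        r2=r2,
        t2=t2,
        b1=scatter(res["b1_fraction"] * 100.0),
        s0=scatter(res["s0"]),
        residual=scatter(res["residual"]),
        total_cost=scatter(res["total_cost"]),
        excluded=excluded,
        snr=None if snr is None else snr.snr,
        provenance={
            "dictionary_fingerprint": dictionary.fingerprint,
            "lambda": config.lam if b1_reg is not None else 0.0,
            "snr_threshold": config.snr_threshold,
            "regularized": b1_reg is not None,
        },
    )
    for vol in (mapset.b1, mapset.s0, mapset.residual, mapset.total_cost):
        vol[excluded] = np.nan
    return mapset


def two_pass_fit(stack: np.ndarray, dictionary: Dictionary,
                 afi: B1Maps, config: MatchConfig | None = None,
                 snr: SNRMap | None = None) -> tuple[MapSet, B1Maps]:
    """EMC-then-regularized matching.

    Pass 1 matches without any B1 penalty to obtain B1_EMC, which is
    Gaussian-smoothed and blended with the AFI estimate using the
    zeta-confidence weight; pass 2 re-matches with the blended B1_REG as the
    regularizer.  Returns the final MapSet and the completed B1Maps.
    """
    config = config or MatchConfig()
    pass1 = match_voxels(stack, dictionary, None, config, snr)
    b1_emc = smooth_emc_b1(pass1.b1, config.b1_smooth_sigma)
    b1_reg = combine_b1(afi.b1_afi, b1_emc, afi.zeta, config.zeta_th)
    maps = B1Maps(b1_afi=afi.b1_afi, zeta=afi.zeta, b1_emc=b1_emc,
                  b1_reg=b1_reg, valid=afi.valid)
    final = match_voxels(stack, dictionary, b1_reg, config, snr)
    final.provenance["zeta_th"] = config.zeta_th
    final.provenance["b1_smooth_sigma"] = config.b1_smooth_sigma
    return final, maps
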