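"""End-to-end study pipeline: noise -> denoise/correct -> B1 -> regularized fit.

Mirrors the processing flow the mapping method prescribes, minus acquisition
and registration (input grids are assumed co-registered): estimate per-slice
nc-chi noise, patch-PCA denoise and bias-correct the echo stack, derive the
AFI B1 map and its confidence, run the two-pass (EMC then regularized)
dictionary match, and write all maps plus a QC report.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .b1map import B1Maps, afi_b1_map, afi_error_map
from .denoise import PatchConfig, denoise_and_correct
from .dictionary import Dictionary, load_dictionary
from .io import read_mese, read_volume, write_json, write_volume
from .match import MapSet, MatchConfig, two_pass_fit, match_voxels
from .noise import estimate_noise, snr_map
from .sequence import AFIProtocol, MESEProtocol

log = logging.getLogger("emct2")


@dataclass
class StudyConfig:
    """Resolved inputs and options of one pipeline run."""

    mese_path: str
    dictionary_path: str
    out_dir: str
    afi_s1_path: str | None = None
    afi_s2_path: str | None = None
    b1_map_path: str | None = None          # precomputed regularizer (percent)
    truth_labels_path: str | None = None    # optional vial labels for QC recovery
    truth_r2_path: str | None = None
    afi: AFIProtocol = field(default_factory=AFIProtocol)
    match: MatchConfig = field(default_factory=MatchConfig)
    patch: PatchConfig | None = None
    background_mask_path: str | None = None
    seed: int = 0
    skip_denoise: bool = False

    def validate(self) -> None:
        for name in ("mese_path", "dictionary_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        has_afi = self.afi_s1_path and self.afi_s2_path
        if has_afi and self.b1_map_path:
            raise ValueError("give either an AFI pair or a precomputed B1 map, not both")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: StudyConfig) -> MapSet:
    """Execute the full mapping pipeline and write outputs under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(out / "config.json", {"config": config.to_dict(), "version": __version__})
    t_start = time.time()
    stage = "load"
    try:
        stack, affine, sidecar = read_mese(config.mese_path)
        dictionary = load_dictionary(config.dictionary_path)
        if dictionary.etl != stack.shape[3]:
            raise ValueError(
                f"stack has {stack.shape[3]} echoes, dictionary {dictionary.etl}")

        stage = "noise-estimation"
        bg_mask = None
        if config.background_mask_path:
            bg_mask = read_volume(config.background_mask_path)[0] > 0
        noise = estimate_noise(stack, background_mask=bg_mask)
        snr = snr_map(stack, noise, threshold=config.match.snr_threshold)
        write_volume(out / "snr.nii.gz", snr.snr, affine)
        write_json(out / "noise.json", {
            "n_eff": noise.n_eff, "sigma_eff": noise.sigma_eff,
            "diagnostics": noise.diagnostics,
        })

        stage = "denoise"
        if config.skip_denoise:
            fit_input = stack
        else:
            patch = config.patch or PatchConfig.for_etl(stack.shape[3])
            result = denoise_and_correct(stack, noise, patch)
            fit_input = result.corrected
            write_volume(out / "denoised.nii.gz", result.denoised, affine)
            write_volume(out / "corrected.nii.gz", result.corrected, affine)

        stage = "b1-mapping"
        b1maps = None
        if config.afi_s1_path and config.afi_s2_path:
            s1 = read_volume(config.afi_s1_path)[0]
            s2 = read_volume(config.afi_s2_path)[0]
            afi_stack = np.stack([s1, s2], axis=3)
            afi_noise = estimate_noise(afi_stack)
            sig = np.repeat(afi_noise.sigma_eff[None, None, :], s1.shape[0], 0)
            sig = np.repeat(sig, s1.shape[1], 1)
            b1_afi, valid = afi_b1_map(s1, s2, config.afi)
            zeta = afi_error_map(s1, s2, sig, sig, config.afi)
            b1maps = B1Maps(b1_afi=b1_afi, zeta=zeta, valid=valid)
            write_volume(out / "b1_afi.nii.gz", b1_afi, affine)
            write_volume(out / "zeta.nii.gz", zeta, affine)

        stage = "matching"
        if b1maps is not None:
            mapset, b1maps = two_pass_fit(fit_input, dictionary, b1maps,
                                          config.match, snr)
            write_volume(out / "b1_emc.nii.gz", b1maps.b1_emc, affine)
            write_volume(out / "b1_reg.nii.gz", b1maps.b1_reg, affine)
        elif config.b1_map_path:
            b1_reg = read_volume(config.b1_map_path)[0]
            mapset = match_voxels(fit_input, dictionary, b1_reg, config.match, snr)
        else:
            mapset = match_voxels(fit_input, dictionary, None, config.match, snr)

        stage = "write"
        for name, vol in (("r2_map", mapset.r2), ("t2_map", mapset.t2),
                          ("b1_map", mapset.b1), ("s0_map", mapset.s0),
                          ("residual", mapset.residual),
                          ("total_cost", mapset.total_cost)):
            write_volume(out / f"{name}.nii.gz", vol, affine)
        write_volume(out / "exclusion_mask.nii.gz",
                     mapset.excluded.astype(np.uint8), affine, dtype=np.uint8)
        mapset.provenance.update({
            "seed": config.seed, "version": __version__,
            "elapsed_s": time.time() - t_start, "sidecar": sidecar,
        })
        write_json(out / "provenance.json", mapset.provenance)

        stage = "qc"
        qc = qc_report(mapset, snr.snr, config)
        write_json(out / "qc.json", qc)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed in stage '{stage}'; completed artifacts are in {out}"
        ) from err
    return mapset


def qc_report(mapset: MapSet, snr: np.ndarray, config: StudyConfig) -> dict:
    """Summary statistics: SNR histogram, exclusions, residuals, vial recovery."""
    hist, edges = np.histogram(snr[np.isfinite(snr)], bins=20)
    finite_res = mapset.residual[np.isfinite(mapset.residual)]
    qc = {
        "snr_histogram": {"counts": hist, "edges": edges},
        "excluded_fraction": float(mapset.excluded.mean()),
        "residual": {} if finite_res.size == 0 else {
            "median": float(np.median(finite_res)),
            "p95": float(np.percentile(finite_res, 95)),
        },
    }
    if config.truth_labels_path and config.truth_r2_path:
        labels = read_volume(config.truth_labels_path)[0].astype(int)
        r2_true = read_volume(config.truth_r2_path)[0]
        recovery = []
        for vid in np.unique(labels[labels > 0]):
            sel = (labels == vid) & np.isfinite(mapset.r2)
            if not sel.any():
                recovery.append({"vial": int(vid), "n": 0})
                continue
            est = float(np.mean(mapset.r2[sel]))
            true = float(np.mean(r2_true[labels == vid]))
            recovery.append({
                "vial": int(vid), "n": int(sel.sum()), "r2_true": true,
                "r2_est": est, "rel_error": (est - true) / true if true else np.nan,
            })
        qc["vial_recovery"] = recovery
    return qc
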