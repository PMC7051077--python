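"""End-to-end orchestration: frames -> chromaticity -> SCB -> screening.

Step 1 turns flash/no-flash raw pairs into one ambient-independent sclera
chromaticity per subject (ROI medians, exposure normalization, ambient
subtraction with the 1% validity filter, per-subject median aggregation,
screen-trained RGB->XYZ mapping).  Step 2 fits the SCB models against TSB
and evaluates screening performance (ROC/AUC, Youden cut-off, confusion
metrics, Bland-Altman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ambient as amb
from .ambient import (
    DEFAULT_THRESHOLD_FRAC,
    FlashPairRGB,
    SubjectUnmeasurableError,
    SubtractionResult,
)
from .colorimetry import (
    CharacterizationMatrix,
    Chromaticity,
    Spectrum,
    fit_characterization,
    jeci,
    rgb_to_xyz,
    spectrum_to_xyz,
    standard_observer,
    xyz_to_chromaticity,
)
from .raw_frames import LinearRGB, RawFrame, ROIMask, extract_roi_rgb, load_raw_frame, saturation_flag
from .scb_models import FitReport, SubjectRecord, fit_scb_jeci, fit_scb_xy
from .screening import (
    bland_altman,
    confusion_at,
    metrics_from_confusion,
    roc_curve,
    youden_optimal,
)
from .simulate import CameraModel, CohortResult, IlluminantPreset, render_patch

logger = logging.getLogger(__name__)

DEFAULT_TSB_THRESHOLDS = (205.0, 250.0)

__all__ = [
    "training_reflectances",
    "characterize_camera",
    "process_pair",
    "estimate_subject",
    "full_frame_roi",
    "cohort_to_records",
    "estimate_from_manifest",
    "analyze_records",
    "records_to_frame",
    "records_from_frame",
]


# ---------------------------------------------------------------------------
# Characterization
# ---------------------------------------------------------------------------


def training_reflectances(grid: np.ndarray) -> list[Spectrum]:
    """A synthetic characterization card: smooth reflectances spanning
    neutrals, broad colours, and the yellow (blue-absorbing) series the
    sclera measurement cares about."""
    wl = np.asarray(grid, dtype=float)
    out: list[Spectrum] = []
    for level in (0.05, 0.2, 0.4, 0.6, 0.8, 0.95):
        out.append(Spectrum(wl, np.full_like(wl, level)))
    for center in (430, 470, 510, 550, 590, 630, 670):
        bump = 0.15 + 0.7 * np.exp(-0.5 * ((wl - center) / 45.0) ** 2)
        out.append(Spectrum(wl, bump))
        notch = np.clip(0.9 - 0.6 * np.exp(-0.5 * ((wl - center) / 55.0) ** 2), 0, 1)
        out.append(Spectrum(wl, notch))
    for strength in (0.05, 0.15, 0.3, 0.5):
        band = np.exp(-0.5 * ((wl - 460.0) / 35.0) ** 2)
        out.append(Spectrum(wl, 0.9 * 10.0 ** (-strength * band)))
    return out


def characterize_camera(
    camera: CameraModel,
    screen: IlluminantPreset,
    exposure: float = 1 / 30,
) -> CharacterizationMatrix:
    """One-time 3x3 RGB->XYZ characterization for the screen illuminant.

    Training RGBs are noiseless renders of the synthetic card under the
    screen; training XYZs are standard-observer integrals of the same
    card under the same screen.  After ambient subtraction the effective
    illuminant is always the screen, so this matrix is the right one for
    every subtracted measurement regardless of the ambient.
    """
    wl = camera.grid
    cmfs = standard_observer(wl)
    spd = screen.effective_spd()
    rgbs, xyzs = [], []
    for refl in training_reflectances(wl):
        rgbs.append(render_patch(refl, [screen], camera, exposure).as_array())
        xyzs.append(np.asarray(spectrum_to_xyz(spd, refl, cmfs)))
    return fit_characterization(rgbs, xyzs, illuminant_tag=screen.name)


# ---------------------------------------------------------------------------
# Step 1: chromaticity estimation
# ---------------------------------------------------------------------------


def full_frame_roi(frame: RawFrame, label: str = "full") -> ROIMask:
    """An ROI covering every mosaic site of a frame (for uniform synthetic
    patches)."""
    h, w = frame.shape
    return ROIMask.from_coords(((r, c) for r in range(h) for c in range(w)), label=label)


def process_pair(
    flash: RawFrame,
    noflash: RawFrame,
    roi_flash: ROIMask,
    roi_noflash: Optional[ROIMask] = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> SubtractionResult:
    """ROI medians, exposure normalization and ambient subtraction for one
    flash/no-flash pair; saturation in either ROI invalidates the pair."""
    roi_noflash = roi_flash if roi_noflash is None else roi_noflash
    flash_rgb = extract_roi_rgb(flash, roi_flash)
    noflash_rgb = extract_roi_rgb(noflash, roi_noflash)
    pair = amb.exposure_normalize(
        FlashPairRGB(
            flash_rgb=flash_rgb,
            noflash_rgb=noflash_rgb,
            exposure_flash=flash.exposure_time,
            exposure_noflash=noflash.exposure_time,
        )
    )
    if saturation_flag(flash, roi_flash) or saturation_flag(noflash, roi_noflash):
        diff = pair.flash_rgb.as_array() - pair.noflash_rgb.as_array()
        return SubtractionResult(LinearRGB(*diff), valid=False, reject_reason="saturated")
    return amb.subtract_pair(pair, threshold_frac=threshold_frac)


@dataclass(frozen=True)
class SubjectEstimate:
    """Aggregated chromaticity estimate for one subject."""

    subject_id: str
    chromaticity: Chromaticity
    jeci: float
    rgb: LinearRGB
    n_valid: int
    n_rejected: int
    reject_reasons: tuple[str, ...]


def estimate_subject(
    subject_id: str,
    results: Sequence[SubtractionResult],
    characterization: CharacterizationMatrix,
) -> SubjectEstimate:
    """Median-aggregate the valid triplets and map to chromaticity."""
    rgb = amb.aggregate_subject(results)
    chrom = xyz_to_chromaticity(rgb_to_xyz(rgb, characterization))
    rejected = [r.reject_reason for r in results if not r.valid]
    return SubjectEstimate(
        subject_id=subject_id,
        chromaticity=chrom,
        jeci=jeci(chrom),
        rgb=rgb,
        n_valid=sum(1 for r in results if r.valid),
        n_rejected=len(rejected),
        reject_reasons=tuple(rejected),
    )


def _flash_only_estimate(
    subject_id: str,
    flash_rgbs: Sequence[LinearRGB],
    characterization: CharacterizationMatrix,
) -> SubjectEstimate:
    """No-subtraction baseline: chromaticity straight from the flash
    (ambient + screen) frames, median-aggregated."""
    med = LinearRGB(*np.median([r.as_array() for r in flash_rgbs], axis=0))
    chrom = xyz_to_chromaticity(rgb_to_xyz(med, characterization))
    return SubjectEstimate(
        subject_id=subject_id,
        chromaticity=chrom,
        jeci=jeci(chrom),
        rgb=med,
        n_valid=len(flash_rgbs),
        n_rejected=0,
        reject_reasons=(),
    )


def cohort_to_records(
    cohort: CohortResult,
    characterization: Optional[CharacterizationMatrix] = None,
    use_subtraction: bool = True,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> tuple[list[SubjectRecord], list[str]]:
    """Run Step 1 over a simulated cohort.

    Returns the per-subject records (chromaticity + truth TSB) and the
    ids of subjects excluded because no valid pair remained.  With
    ``use_subtraction=False`` the flash frames are used directly -- the
    degraded baseline that quantifies what subtraction buys.
    """
    if characterization is None:
        characterization = characterize_camera(cohort.camera, cohort.screen)
    records: list[SubjectRecord] = []
    excluded: list[str] = []
    tsb_by_id = dict(
        zip(cohort.subjects["subject_id"], cohort.subjects["tsb_umol_per_L"])
    )
    for subject_id, pairs in cohort.pairs.items():
        try:
            if use_subtraction:
                results = [
                    process_pair(
                        p.flash_frame,
                        p.noflash_frame,
                        full_frame_roi(p.flash_frame),
                        threshold_frac=threshold_frac,
                    )
                    for p in pairs
                ]
                est = estimate_subject(subject_id, results, characterization)
            else:
                flash_rgbs = [
                    extract_roi_rgb(p.flash_frame, full_frame_roi(p.flash_frame))
                    for p in pairs
                ]
                est = _flash_only_estimate(subject_id, flash_rgbs, characterization)
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    chromaticity=est.chromaticity,
                    jeci=est.jeci,
                    tsb=tsb_by_id[subject_id],
                )
            )
        except (SubjectUnmeasurableError, ValueError) as err:
            logger.info("subject %s excluded: %s", subject_id, err)
            excluded.append(subject_id)
    return records, excluded


def estimate_from_manifest(
    manifest_path: str | Path,
    characterization: CharacterizationMatrix,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Run Step 1 over a capture manifest on disk.

    The manifest is a CSV with columns ``subject_id, flash_image,
    flash_sidecar, noflash_image, noflash_sidecar, roi_file`` (paths
    relative to the manifest).  Multiple rows per subject are independent
    measurements.  Failing subjects are skipped with a logged reason; an
    empty result is an error.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {
        "subject_id",
        "flash_image",
        "flash_sidecar",
        "noflash_image",
        "noflash_sidecar",
        "roi_file",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    if df.empty:
        raise ValueError("manifest is empty")
    base = manifest_path.parent
    rows = []
    for subject_id, group in df.groupby("subject_id", sort=True):
        results = []
        try:
            for _, row in group.iterrows():
                flash = load_raw_frame(base / row["flash_image"], base / row["flash_sidecar"])
                noflash = load_raw_frame(
                    base / row["noflash_image"], base / row["noflash_sidecar"]
                )
                roi = ROIMask.from_json(base / row["roi_file"])
                results.append(
                    process_pair(flash, noflash, roi, threshold_frac=threshold_frac)
                )
            est = estimate_subject(str(subject_id), results, characterization)
        except (OSError, ValueError, SubjectUnmeasurableError) as err:
            logger.warning("subject %s skipped: %s", subject_id, err)
            continue
        row_out = {
            "subject_id": est.subject_id,
            "x": est.chromaticity.x,
            "y": est.chromaticity.y,
            "z": est.chromaticity.z,
            "jeci": est.jeci,
            "n_valid": est.n_valid,
            "n_rejected": est.n_rejected,
        }
        if "tsb_umol_per_L" in group.columns:
            row_out["tsb_umol_per_L"] = float(group["tsb_umol_per_L"].iloc[0])
        rows.append(row_out)
    if not rows:
        raise ValueError("no subject in the manifest produced a valid estimate")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Step 2: SCB fitting and screening
# ---------------------------------------------------------------------------


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "x": [r.chromaticity.x for r in records],
            "y": [r.chromaticity.y for r in records],
            "z": [r.chromaticity.z for r in records],
            "jeci": [r.jeci for r in records],
            "tsb_umol_per_L": [r.tsb for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    required = {"subject_id", "x", "y", "z", "tsb_umol_per_L"}
    if not required.issubset(df.columns):
        raise ValueError(f"subject table missing columns: {sorted(required - set(df.columns))}")
    return [
        SubjectRecord.from_chromaticity(
            str(row.subject_id),
            Chromaticity(float(row.x), float(row.y), float(row.z)),
            float(row.tsb_umol_per_L),
        )
        for row in df.itertuples()
    ]


def analyze_records(
    records: Sequence[SubjectRecord],
    tsb_thresholds: Sequence[float] = DEFAULT_TSB_THRESHOLDS,
    scb_cutoff: Optional[float] = None,
) -> dict:
    """Fit both SCB models and evaluate SCB_xy as a screening test.

    For each TSB threshold, reports the ROC (AUC), the Youden-optimal
    cut-off (or a caller-fixed one), the confusion matrix and the derived
    metrics with exact 95% CIs, plus Bland-Altman agreement of SCB_xy
    against TSB.
    """
    report_jeci = fit_scb_jeci(records)
    report_xy = fit_scb_xy(records)
    x = np.array([r.chromaticity.x for r in records])
    y = np.array([r.chromaticity.y for r in records])
    tsb = np.array([r.tsb for r in records])
    model = report_xy.model
    scb = model.p * x + model.q * y + model.r_intercept

    screening = {}
    for thr in tsb_thresholds:
        roc = roc_curve(scb, tsb, thr)
        cutoff = youden_optimal(roc) if scb_cutoff is None else float(scb_cutoff)
        counts = confusion_at(scb, tsb, cutoff, thr)
        metrics = metrics_from_confusion(counts)
        screening[str(int(thr))] = {
            "tsb_threshold_umol_per_L": thr,
            "auc": roc.auc,
            "scb_cutoff_umol_per_L": cutoff,
            "confusion": {
                "tp": counts.tp,
                "fn": counts.fn,
                "tn": counts.tn,
                "fp": counts.fp,
            },
            "metrics": metrics.to_dict(),
        }
    ba = bland_altman(scb, tsb)
    return {
        "schema_version": 1,
        "n_subjects": len(records),
        "models": {
            "scb_jeci": report_jeci.to_dict(),
            "scb_xy": report_xy.to_dict(),
        },
        "screening": screening,
        "bland_altman": {
            "bias_umol_per_L": ba.bias,
            "loa_low_umol_per_L": ba.loa_low,
            "loa_high_umol_per_L": ba.loa_high,
        },
    }
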