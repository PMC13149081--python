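"""Two-stage patient-level inference.

Segmentation network -> predicted tumor mask -> shift-window patches from
the mask -> patch-wise genotype probabilities -> crop-and-stitch aggregation
to a probability map restricted to the ROI -> patient-level summary by
probability mean (P_mean, the primary continuous metric) and pixel-wise
majority vote (threshold 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patching import aggregate_patches, build_grid, extract_patches
from .phantom import CESTVolume


class EmptyROIError(ValueError):
    pass


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities restricted to an ROI."""

    probs: np.ndarray  # (H, W, N)
    roi: np.ndarray  # (H, W) bool
    valid: np.ndarray  # (H, W) bool, pixels with >= 1 patch contribution

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, bool)
        self.valid = np.asarray(self.valid, bool)
        if self.probs.shape[:2] != self.roi.shape:
            raise ValueError("probability map and ROI shapes differ")
        if np.any(self.roi & ~self.valid):
            raise ValueError("ROI contains pixels with no patch contribution")


@dataclass
class PatientPrediction:
    """Patient-level genotype summary."""

    patient_id: str | None
    p_mean: tuple[float, ...]  # per class
    vote: int
    n_pixels: int
    n_patches: int


def segment_patient(volume: CESTVolume, model) -> np.ndarray:
    """Binary tumor mask from the segmentation model (argmax of the 2-class
    map; exact 0.5/0.5 ties break to background)."""
    probs = model.predict_proba_images(volume.data[None].astype(np.float32))[0]
    return probs[..., 1] > 0.5


def p_mean(pmap: ProbabilityMap, cls: int) -> float:
    """Arithmetic mean of the class-``cls`` probability over ROI pixels."""
    if not pmap.roi.any():
        raise EmptyROIError("empty ROI")
    return float(pmap.probs[pmap.roi, cls].mean())


def majority_vote(pmap: ProbabilityMap, threshold: float = 0.5) -> int:
    """Pixel votes are ``P(class 1) >= threshold``; the patient is labelled 1
    iff more than half the ROI pixels vote 1 (an exact half ties to 0)."""
    if not pmap.roi.any():
        raise EmptyROIError("empty ROI")
    votes = pmap.probs[pmap.roi, 1] >= threshold
    return int(votes.mean() > 0.5)


def predict_genotype_patient(
    volume: CESTVolume,
    mask: np.ndarray,
    model,
    patch_size: int = 48,
    stride: int = 12,
    crop: int | None = None,
    patient_id: str | None = None,
) -> tuple[PatientPrediction, ProbabilityMap]:
    """Patch, predict, stitch and summarize one patient.

    ``crop`` defaults to the stride.  Deterministic given the model and
    inputs.  Raises :class:`EmptyROIError` for an empty mask (the caller
    skips the patient with explicit status).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyROIError("empty tumor mask; patient skipped")
    if crop is None:
        crop = stride
    grid = build_grid(mask, volume.shape, patch_size, stride)
    patches = extract_patches(volume, grid, patient_id=patient_id)
    probs = model.predict_proba_patches(patches.patches.astype(np.float32))
    stitched, valid = aggregate_patches(np.asarray(probs, np.float64), grid, crop)
    pmap = ProbabilityMap(probs=stitched, roi=mask & valid, valid=valid)
    pm = tuple(p_mean(pmap, c) for c in range(stitched.shape[-1]))
    pred = PatientPrediction(
        patient_id=patient_id,
        p_mean=pm,
        vote=majority_vote(pmap),
        n_pixels=int(pmap.roi.sum()),
        n_patches=len(grid),
    )
    return pred, pmap


def predict_cohort(
    records,
    seg_model,
    geno_model,
    task: str = "idh",
    patch_size: int = 48,
    stride: int = 12,
    use_true_masks: bool = False,
) -> tuple[list[PatientPrediction], list[str]]:
    """Run the two-stage pipeline over a cohort.

    Returns per-patient predictions plus the ids of patients excluded
    because their predicted segmentation was empty.
    """
    preds: list[PatientPrediction] = []
    excluded: list[str] = []
    for rec in records:
        mask = rec.tumor_mask if use_true_masks else segment_patient(rec.volume, seg_model)
        try:
            pred, _ = predict_genotype_patient(
                rec.volume, mask, geno_model,
                patch_size=patch_size, stride=stride, patient_id=rec.patient_id,
            )
        except EmptyROIError:
            excluded.append(rec.patient_id)
            continue
        preds.append(pred)
    return preds, excluded
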