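"""Serial-section lesion volumetry.

Lesion area is measured per coronal section on the degeneration-stain
channel (bright signal over dark background), then integrated across the
anterior-posterior (AP) axis with the truncated-cone (conical frustum)
rule: consecutive sections with areas A1, A2 a sagittal distance h apart
contribute V = h/3 * (A1 + A2 + sqrt(A1*A2)). The most caudal section with
lesion signal gives the caudal lesion border relative to bregma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .imaging import SectionImage


@dataclass
class LesionMask:
    """Binary lesion mask aligned to one section."""

    mask: np.ndarray
    source: str  # "segmented" or "provided"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class VolumeEstimate:
    """Per-section lesion areas and the integrated volume for one animal."""

    per_section: list[tuple[float, float]]  # (ap_mm, area_mm2), sorted by ap
    volume_mm3: float
    caudal_border_mm: float | None  # None = no lesion found


def segment_lesion(section: SectionImage,
                   method: str = "otsu",
                   provided_mask: np.ndarray | None = None,
                   min_area_mm2: float = 0.01,
                   min_contrast_sigmas: float = 8.0) -> LesionMask:
    """Delineate the lesion on a degeneration-stain section.

    ``method`` is ``"otsu"`` (automatic global threshold), ``"fixed:<t>"``
    (absolute gray-value threshold) or ``"provided"`` (pass a manual mask
    through unchanged, preserving a manual-tagging workflow). For the
    automatic methods, connected components smaller than ``min_area_mm2``
    are removed as noise.

    Otsu always splits a histogram, even of pure background; the split is
    only accepted when the foreground-class mean lies ``min_contrast_sigmas``
    robust SDs (MAD) above the image median, so lesion-free sections yield
    empty masks.
    """
    if section.channel != "fjc":
        raise ValueError("lesion segmentation runs on the fjc channel")
    if method == "provided" or provided_mask is not None:
        if provided_mask is None:
            raise ValueError("method 'provided' requires provided_mask")
        provided_mask = np.asarray(provided_mask, dtype=bool)
        if provided_mask.shape != section.shape:
            raise ValueError(
                f"mask shape {provided_mask.shape} != image {section.shape}")
        return LesionMask(mask=provided_mask, source="provided")

    img = np.asarray(section.pixels, dtype=float)
    if method == "otsu":
        if np.ptp(img) == 0:  # uniform image: nothing to segment
            return LesionMask(np.zeros(section.shape, bool), "segmented")
        t = threshold_otsu(img)
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        fg_mean = float(img[img > t].mean()) if (img > t).any() else med
        if fg_mean < med + min_contrast_sigmas * sigma:
            return LesionMask(np.zeros(section.shape, bool), "segmented")
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = img > t
    min_px = max(1, int(round(min_area_mm2 / (section.um_per_px / 1000.0) ** 2)))
    if min_px > 1:
        mask = remove_small_objects(mask, max_size=min_px - 1)
    return LesionMask(mask=mask, source="segmented")


def lesion_area(mask: LesionMask | np.ndarray, um_per_px: float) -> float:
    """Lesion area in mm²: true-pixel count times the pixel area."""
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    return float(m.sum()) * (um_per_px / 1000.0) ** 2


def _check_sorted(per_section: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    pairs = [(float(ap), float(a)) for ap, a in per_section]
    aps = [ap for ap, _ in pairs]
    if sorted(aps) == aps and len(set(aps)) == len(aps):
        return pairs
    if sorted(aps, reverse=True) == aps and len(set(aps)) == len(aps):
        return pairs[::-1]
    raise ValueError("ap positions must be strictly monotone")


def stack_volume(per_section: Sequence[tuple[float, float]],
                 end_caps: bool = True,
                 cap_height_mm: float | None = None) -> float:
    """Integrate per-section areas into a volume (mm³) by the frustum rule.

    Each consecutive pair of sections contributes a conical frustum
    ``h/3 * (A1 + A2 + sqrt(A1*A2))`` with ``h`` the AP distance between
    them. When ``end_caps`` is on and a terminal section still has nonzero
    area, the lesion is closed off with a cone of height ``cap_height_mm``
    (default: the spacing to that end's neighbouring section, i.e. the
    local analysis spacing).
    """
    pairs = _check_sorted(per_section)
    if len(pairs) < 2:
        raise ValueError("need at least two sections")
    if any(a < 0 for _, a in pairs):
        raise ValueError("areas must be non-negative")
    vol = 0.0
    for (ap1, a1), (ap2, a2) in zip(pairs, pairs[1:]):
        h = ap2 - ap1
        vol += h / 3.0 * (a1 + a2 + math.sqrt(a1 * a2))
    if end_caps:
        for end, neighbour in ((pairs[0], pairs[1]), (pairs[-1], pairs[-2])):
            if end[1] > 0:
                h = cap_height_mm if cap_height_mm is not None else abs(
                    neighbour[0] - end[0])
                vol += end[1] * h / 3.0
    return vol


def caudal_border(per_section: Sequence[tuple[float, float]],
                  min_area_mm2: float = 0.0) -> float | None:
    """Most caudal AP (mm from bregma, smallest value) with lesion area
    above ``min_area_mm2``; ``None`` when no section is lesioned."""
    lesioned = [ap for ap, a in per_section if a > min_area_mm2]
    return min(lesioned) if lesioned else None


def measure_stack(sections: Sequence[SectionImage],
                  method: str = "otsu",
                  masks: Sequence[np.ndarray] | None = None,
                  min_area_mm2: float = 0.01,
                  end_caps: bool = True) -> VolumeEstimate:
    """Segment every section, integrate the volume and locate the caudal
    border in one call. ``masks`` supplies manual delineations (one per
    section) instead of automatic segmentation."""
    fjc = [s for s in sections if s.channel == "fjc"]
    if masks is not None and len(masks) != len(fjc):
        raise ValueError("need one provided mask per fjc section")
    per = []
    for i, s in enumerate(sorted(fjc, key=lambda s: s.ap_mm)):
        if masks is not None:
            m = segment_lesion(s, method="provided", provided_mask=masks[i])
        else:
            m = segment_lesion(s, method=method, min_area_mm2=min_area_mm2)
        per.append((s.ap_mm, lesion_area(m, s.um_per_px)))
    return VolumeEstimate(
        per_section=per,
        volume_mm3=stack_volume(per, end_caps=end_caps),
        caudal_border_mm=caudal_border(per),
    )
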