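"""Section-image container and TIFF + JSON sidecar I/O.

A histological dataset is a stack of coronal-section grayscale images, one
per anterior-posterior (AP) position, with spatial metadata tying pixel
space to stereotaxic space: AP position in mm relative to bregma (positive
= rostral), pixel pitch in µm, the pixel column of the anatomical midline,
and which hemisphere carries the lesion.

On disk a stack is a multi-page TIFF (one page per section per channel)
plus a JSON sidecar with the per-page metadata, so the images remain
readable by any TIFF viewer while the analysis stays fully parameterized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

VALID_SIDES = ("left", "right")
VALID_CHANNELS = ("fjc", "iba1")


@dataclass
class SectionImage:
    """One coronal section: a 2-D grayscale image plus spatial metadata.

    Parameters
    ----------
    pixels
        2-D intensity array (any numeric dtype; 8-bit on disk).
    ap_mm
        Anterior-posterior position in mm from bregma, positive rostral.
    um_per_px
        Pixel pitch in µm (isotropic).
    midline_col
        Pixel column of the anatomical midline.
    lesion_side
        ``"left"`` or ``"right"``: the hemisphere containing the lesion.
    channel
        ``"fjc"`` (degenerating neurons; lesion delineation) or
        ``"iba1"`` (microglial marker; reactivity scoring).
    animal_id
        Identifier used in all output tables.
    """

    pixels: np.ndarray
    ap_mm: float
    um_per_px: float
    midline_col: int
    lesion_side: str
    channel: str
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not (0 <= self.midline_col < self.pixels.shape[1]):
            raise ValueError("midline_col must lie inside the image")
        if self.lesion_side not in VALID_SIDES:
            raise ValueError(f"lesion_side must be one of {VALID_SIDES}")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def metadata(self) -> dict:
        return {
            "ap_mm": float(self.ap_mm),
            "um_per_px": float(self.um_per_px),
            "midline_col": int(self.midline_col),
            "lesion_side": self.lesion_side,
            "channel": self.channel,
            "animal_id": self.animal_id,
        }


def write_stack(path: str | Path, sections: Sequence[SectionImage],
                extra: dict | None = None) -> None:
    """Write sections as a multi-page 8-bit TIFF plus a ``.json`` sidecar.

    Pages are written in the order given; the sidecar lists one metadata
    record per page (same order) plus any ``extra`` payload (e.g. a
    ground-truth record for synthetic data).
    """
    path = Path(path)
    pages = []
    for s in sections:
        img = np.clip(np.round(np.asarray(s.pixels, dtype=float)), 0, 255)
        pages.append(img.astype(np.uint8))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    sidecar = {"pages": [s.metadata() for s in sections]}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> tuple[list[SectionImage], dict]:
    """Read a multi-page TIFF + sidecar written by :func:`write_stack`.

    Returns the sections and the full sidecar dict (which may carry extra
    keys such as a ground-truth record).
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    meta = sidecar["pages"]
    if len(meta) != len(pages):
        raise ValueError(
            f"sidecar lists {len(meta)} pages but TIFF has {len(pages)}")
    sections = [SectionImage(pixels=img, **m) for img, m in zip(pages, meta)]
    return sections, sidecar
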