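"""The atomic image container carried through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SectionImage:
    """One 2-D RGB section with resolution metadata.

    Attributes
    ----------
    data : ndarray
        ``(H, W, 3)`` uint8 RGB array (or ``(H, W)`` grayscale).
    mpp : float
        Microns per pixel at this resolution level (0.25 at a 40x scan,
        0.5 at the 20x working level).
    origin : tuple of float
        ``(x0, y0)`` offset of this image's pixel (0, 0) in its parent
        image, in parent pixels.  (0, 0) for a full section; set by
        ``crop_ribbon`` so ribbon coordinates map back to the slide.
    """

    data: np.ndarray
    mpp: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D image array, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("zero-size image")
        if self.mpp <= 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def to_gray(self) -> np.ndarray:
        """Luma grayscale as float in [0, 1]."""
        d = self.data.astype(float) / 255.0
        if d.ndim == 2:
            return d
        return d[..., :3] @ np.array([0.2125, 0.7154, 0.0721])


def as_section(img, mpp: float = 1.0) -> SectionImage:
    """Coerce an ndarray (or pass through a SectionImage) to SectionImage."""
    if isinstance(img, SectionImage):
        return img
    return SectionImage(data=np.asarray(img), mpp=mpp)
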