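"""Training-label synthesis and input normalization.

Ground-truth pixel classes for network training are assembled by thresholding
the paired fluorescence channels of a training section: a pixel is *nuclei*
where the nuclear stain exceeds its threshold, else *cytoskeleton* where the
structural stain (F-actin or membrane) exceeds its threshold, else
*background*.  Nuclei win on overlap because the nucleus channel later seeds
the watershed, so its integrity matters most.

Reflectance inputs are rescaled linearly into [0, 1] against a fixed
acquisition range (bit depth), never per-image extremes: train and test
images are acquired with identical microscope settings, and a fixed scale
keeps them on one intensity frame.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from lfseg.types import (
    CLASS_BACKGROUND,
    CLASS_CYTOSKELETON,
    CLASS_NUCLEI,
    NormalizedImage,
    check_same_shape,
)

THRESHOLD_METHODS = ("otsu", "manual")


def _channel_threshold(channel: np.ndarray, method: str, manual: float | None) -> float:
    if method == "manual":
        if manual is None or not np.isfinite(manual):
            raise ValueError("manual thresholding requires a finite threshold value")
        return float(manual)
    if method == "otsu":
        flat = np.asarray(channel, dtype=np.float64)
        if np.ptp(flat) == 0:
            return np.inf  # constant channel: nothing separable, all background
        return float(threshold_otsu(flat))
    raise ValueError(f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}")


def make_class_labels(
    nuclei_fluor: np.ndarray,
    structure_fluor: np.ndarray,
    method: str = "otsu",
    manual_thresholds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Build a three-class label map from paired fluorescence channels.

    Parameters
    ----------
    nuclei_fluor, structure_fluor
        Fluorescence images sharing one shape (2D or 3D).
    method
        ``"otsu"`` (default, parameter-free, per channel) or ``"manual"``.
    manual_thresholds
        ``(nuclei_threshold, structure_threshold)``.  Required for
        ``method="manual"``; if given with ``method="otsu"`` they override
        Otsu (convenience for reproducing a fixed labelling).

    Returns
    -------
    ndarray of uint8
        Per-pixel class in {0 background, 1 nuclei, 2 cytoskeleton}.
        Nuclei take priority where both channels are suprathreshold.
    """
    nuc = np.asarray(nuclei_fluor, dtype=np.float64)
    cyt = np.asarray(structure_fluor, dtype=np.float64)
    shape = check_same_shape(nuc, cyt)

    if manual_thresholds is not None:
        t_nuc, t_cyt = (float(t) for t in manual_thresholds)
        if not (np.isfinite(t_nuc) and np.isfinite(t_cyt)):
            raise ValueError("manual thresholds must be finite")
    else:
        if method not in THRESHOLD_METHODS:
            raise ValueError(
                f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}"
            )
        if method == "manual":
            raise ValueError("method='manual' requires manual_thresholds")
        t_nuc = _channel_threshold(nuc, method, None)
        t_cyt = _channel_threshold(cyt, method, None)

    labels = np.full(shape, CLASS_BACKGROUND, dtype=np.uint8)
    labels[cyt >= t_cyt] = CLASS_CYTOSKELETON
    labels[nuc >= t_nuc] = CLASS_NUCLEI  # nucleus priority on overlap
    return labels


def rescale_unit(
    raw: np.ndarray,
    lo: float | None = None,
    hi: float | None = None,
    pixel_size: float | None = None,
) -> NormalizedImage:
    """Rescale a raw image linearly into [0, 1] with no contrast adjustment.

    ``lo``/``hi`` default to the fixed range of the acquisition bit depth
    (0 and the dtype maximum for integer images; 0 and 1 for float images),
    *not* the per-image min/max.  Output is ``clip((raw - lo)/(hi - lo), 0, 1)``.
    """
    raw = np.asarray(raw)
    if lo is None:
        lo = 0.0
    if hi is None:
        if np.issubdtype(raw.dtype, np.integer):
            hi = float(np.iinfo(raw.dtype).max)
        else:
            hi = 1.0
    lo, hi = float(lo), float(hi)
    if hi <= lo:
        raise ValueError(f"require hi > lo, got lo={lo}, hi={hi}")
    scaled = np.clip((raw.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedImage(pixels=scaled, pixel_size=pixel_size)
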