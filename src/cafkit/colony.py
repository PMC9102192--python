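"""Colony-forming-assay image quantification.

Plates stained with trypan blue are photographed; each image is
registered to a reference image carrying a manually labelled region of
interest, colonies are segmented by thresholding the blue channel with
one fixed threshold for the whole batch, and the fraction of ROI area
covered by colonies is reported. Cocultures are then called
colony-supporting when their covered fraction significantly exceeds the
non-cocultured control (Welch t-test, p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


class ColonyError(ValueError):
    """Invalid input to a colony-quantification routine."""


POOR_REGISTRATION_NCC = 0.2


def _as_rgb(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ColonyError("expected an H×W×3 RGB raster")
    if arr.shape[0] < 64 or arr.shape[1] < 64:
        raise ColonyError("image must be at least 64×64 pixels")
    return arr


def _grayscale(image: np.ndarray) -> np.ndarray:
    """Grayscale as the plain mean of the three channels."""
    return _as_rgb(image).mean(axis=2)


@dataclass
class Registration:
    offset: tuple[int, int]  # (dy, dx): image content = reference shifted by this
    correlation: float
    poor: bool


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation; 0 when either patch is constant."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def register_to_reference(
    image, reference, search_radius: int = 32
) -> Registration:
    """Integer-pixel translation aligning ``image`` to ``reference``.

    Searches all shifts (dy, dx) within the radius for the one
    maximising the normalised cross-correlation of the grayscale
    overlap, i.e. image[y, x] ≈ reference[y − dy, x − dx]. Exact ties
    are broken by smallest |dy| + |dx|, then row-major order. A best
    correlation below 0.2 (including the degenerate constant-image
    case) sets the ``poor`` flag; the result is still returned.
    """
    g_img = _grayscale(image)
    g_ref = _grayscale(reference)
    if g_img.shape != g_ref.shape:
        raise ColonyError("image and reference dimensions differ")
    h, w = g_img.shape
    r = int(search_radius)
    best: tuple[float, int, tuple[int, int]] | None = None
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ys_i = slice(max(0, dy), h + min(0, dy))
            xs_i = slice(max(0, dx), w + min(0, dx))
            ys_r = slice(max(0, -dy), h + min(0, -dy))
            xs_r = slice(max(0, -dx), w + min(0, -dx))
            if ys_i.stop <= ys_i.start or xs_i.stop <= xs_i.start:
                continue
            c = _ncc(g_img[ys_i, xs_i], g_ref[ys_r, xs_r])
            key = (-c, abs(dy) + abs(dx))
            if best is None or key < best[:2]:
                best = (-c, abs(dy) + abs(dx), (dy, dx))
    assert best is not None
    corr = -best[0]
    return Registration(
        offset=best[2], correlation=corr, poor=corr < POOR_REGISTRATION_NCC
    )


def segment_colonies(
    image, threshold: int, *, stain_bright: bool = True
) -> np.ndarray:
    """Boolean colony mask by fixed-threshold on the blue channel.

    A pixel is colony iff its blue value is ≥ threshold (trypan-blue
    stained colonies rendered blue-bright); pass ``stain_bright=False``
    to invert the polarity for dark-stain imagery. The same threshold
    must be applied to every image of a batch.
    """
    if not 0 <= threshold <= 255:
        raise ColonyError("threshold must be within 0–255")
    blue = _as_rgb(image)[:, :, 2]
    return blue >= threshold if stain_bright else blue <= threshold


def area_fraction(
    mask: np.ndarray, roi: np.ndarray, offset: tuple[int, int] = (0, 0)
) -> float:
    """Fraction of ROI pixels covered by the colony mask.

    The ROI is defined on the reference image; ``offset`` (dy, dx) is
    the registration result, so ROI pixel (y, x) maps to mask pixel
    (y + dy, x + dx). ROI pixels mapped outside the image are excluded
    from the denominator.
    """
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if mask.shape != roi.shape:
        raise ColonyError("mask and ROI dimensions differ")
    dy, dx = int(offset[0]), int(offset[1])
    h, w = mask.shape
    ys_m = slice(max(0, dy), h + min(0, dy))
    xs_m = slice(max(0, dx), w + min(0, dx))
    ys_r = slice(max(0, -dy), h + min(0, -dy))
    xs_r = slice(max(0, -dx), w + min(0, -dx))
    roi_in = roi[ys_r, xs_r]
    n_roi = int(roi_in.sum())
    if n_roi == 0:
        raise ColonyError("effective ROI is empty after applying offset")
    covered = int(mask[ys_m, xs_m][roi_in].sum())
    return covered / n_roi


@dataclass
class ColonyResult:
    """Quantification of one plate image against the reference."""

    offset: tuple[int, int]
    correlation: float
    threshold_used: int
    mask: np.ndarray
    area_fraction: float
    flags: list[str] = field(default_factory=list)


def quantify_image(
    image, reference, roi, threshold: int, *,
    search_radius: int = 32, stain_bright: bool = True,
) -> ColonyResult:
    """register → segment → ROI area fraction for one image."""
    reg = register_to_reference(image, reference, search_radius)
    mask = segment_colonies(image, threshold, stain_bright=stain_bright)
    frac = area_fraction(mask, roi, reg.offset)
    flags = ["poor registration"] if reg.poor else []
    return ColonyResult(
        offset=reg.offset,
        correlation=reg.correlation,
        threshold_used=threshold,
        mask=mask,
        area_fraction=frac,
        flags=flags,
    )


@dataclass
class SupportResult:
    p_value: float
    supporting: bool  # p < alpha and treated mean above control
    suppressing: bool  # p < alpha and treated mean below control
    t_statistic: float


def support_test(
    treated: Sequence[float],
    control: Sequence[float],
    alpha: float = 0.05,
) -> SupportResult:
    """Call a coculture colony-supporting vs the non-cocultured control.

    Two-sided Welch t-test on covered-area fractions; supporting when
    p < alpha with a higher treated mean, suppressing when p < alpha
    with a lower treated mean. Identical constant groups give p = 1.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ColonyError("support test needs >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance groups: identical means are a null
        # result, distinct means an infinitely-confident separation
        if a[0] == b[0]:
            return SupportResult(1.0, False, False, 0.0)
        diff = float(a[0] - b[0])
        return SupportResult(0.0, diff > 0, diff < 0, math.copysign(math.inf, diff))
    res = sps.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    t = float(res.statistic)
    diff = a.mean() - b.mean()
    return SupportResult(
        p_value=p,
        supporting=bool(p < alpha and diff > 0),
        suppressing=bool(p < alpha and diff < 0),
        t_statistic=t,
    )
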