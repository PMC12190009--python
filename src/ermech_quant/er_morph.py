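"""ER sheet/tubule morphometry via Renyi-entropy thresholding.

The endoplasmic reticulum images as a mixed network of thin, high-curvature
tubules and brighter, flattened sheets. The quantification pipeline is:

1. convert the ER channel to 8-bit (linear min-max rescale to 0..255);
2. separate ER from background with an automatic Renyi-entropy threshold;
3. separate sheets from tubules, either by a second Renyi threshold within
   the ER mask (sheets image brighter/denser) or by a local-thickness rule;
4. sample three 56-pixel-wide line segments from the nuclear envelope to
   the cell periphery and report the sheet percentage per segment
   (sheet pixels / total ER pixels within the segment);
5. normalise total ER area by the cytoplasm area examined.

The Renyi threshold maximises the sum of foreground and background Renyi
entropies of order alpha over all candidate 8-bit levels; the default
"three-alpha" mode combines the thresholds at alpha = 1/2, 1 and 2 with the
weighting rule of Sahoo, Wilkins & Yeager used by the common ImageJ
implementation (alpha -> 1 reduces to the Shannon / maximum-entropy
threshold of Kapur).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import disk, remove_small_objects

from .errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    SegmentationError,
)

logger = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_TUBULE, LABEL_SHEET = 0, 1, 2


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to the 0..255 range, rounding half-to-even.

    A constant image is a degenerate input: every pixel maps to 0 and a
    warning is logged (no contrast means no threshold can be defined).
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DomainError("image contains non-finite values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        logger.warning("to_8bit: constant image, all pixels map to 0")
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _histogram256(image_or_hist: np.ndarray) -> np.ndarray:
    arr = np.asarray(image_or_hist)
    if arr.ndim == 1 and arr.size == 256:
        if np.any(arr < 0):
            raise FormatError("histogram counts must be non-negative")
        return arr.astype(float)
    if arr.dtype != np.uint8:
        raise FormatError("expected an 8-bit image or a 256-bin histogram")
    return np.bincount(arr.ravel(), minlength=256).astype(float)


def _entropy_curves(hist: np.ndarray, alpha: float) -> np.ndarray:
    """Sum of background+foreground Renyi entropies for every threshold t.

    Threshold t assigns levels <= t to background, > t to foreground.
    Entries where either class is empty are -inf.
    """
    p = hist / hist.sum()
    P1 = np.cumsum(p)  # background mass for threshold t
    P2 = 1.0 - P1
    valid = (P1 > 1e-12) & (P2 > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(alpha - 1.0) < 1e-12:  # Shannon limit (Kapur)
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            c = np.cumsum(plogp)
            hb = np.log(P1) - c / P1
            hf = np.log(P2) - (c[-1] - c) / P2
        else:
            pa = np.where(p > 0, p**alpha, 0.0)
            ca = np.cumsum(pa)
            hb = (np.log(ca) - alpha * np.log(P1)) / (1.0 - alpha)
            hf = (np.log(ca[-1] - ca) - alpha * np.log(P2)) / (1.0 - alpha)
    total = np.where(valid, hb + hf, -np.inf)
    return total


def _single_alpha_threshold(hist: np.ndarray, alpha: float) -> int:
    total = _entropy_curves(hist, alpha)
    if not np.any(np.isfinite(total)):
        raise DegenerateInputError(
            "histogram has fewer than two occupied levels; no threshold exists"
        )
    return int(np.argmax(total))  # argmax ties break toward the lower level


def renyi_threshold(
    image_or_hist: np.ndarray,
    mode: str = "three_alpha",
    alpha: float | None = None,
) -> int:
    """Automatic threshold level in 0..255; foreground is ``level > t``.

    ``mode="single_alpha"`` maximises the summed class Renyi entropies of
    the given order (``alpha=1`` gives the Shannon/Kapur threshold).
    ``mode="three_alpha"`` combines the thresholds at alpha in {1/2, 1, 2}
    with the Sahoo-Wilkins-Yeager weights.
    """
    hist = _histogram256(image_or_hist)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("histogram needs at least two nonzero levels")
    if mode == "single_alpha":
        if alpha is None or alpha <= 0:
            raise DomainError("single_alpha mode requires alpha > 0")
        return _single_alpha_threshold(hist, alpha)
    if mode != "three_alpha":
        raise DomainError(f"unknown Renyi threshold mode {mode!r}")

    ts = sorted(_single_alpha_threshold(hist, a) for a in (0.5, 1.0, 2.0))
    t1, t2, t3 = ts
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    omega = P1[t3] - P1[t1]
    t_opt = (
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (1.0 - P1[t3] + 0.25 * omega * beta[2])
    )
    return int(t_opt)


def _is_bimodal_split(hist: np.ndarray, t: int, depth_ratio: float = 0.5) -> bool:
    """True when threshold ``t`` separates two histogram modes.

    The histogram is lightly smoothed; the minimum density between the
    threshold and the upper class's mode must fall below ``depth_ratio``
    times the smaller of the two class peaks. A threshold cutting through
    a single mode shows no such valley.
    """
    sm = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    # start the upper-class scan past the smoothing half-width so the
    # smeared tail of the lower class cannot masquerade as its density
    lo, hi = sm[: t + 1], sm[t + 3 :]
    if lo.max() <= 0 or hi.size == 0 or hi.max() <= 0:
        return False
    hi_mode = int(np.argmax(hi))
    valley = hi[: hi_mode + 1].min()
    return valley < depth_ratio * min(lo.max(), hi.max())


@dataclass
class ERSegmentation:
    """Background/tubule/sheet label image with the thresholds that made it.

    Labels: 0 background, 1 tubule, 2 sheet. Sheet and tubule partition the
    ER mask; ``threshold_sheet >= threshold_er`` always.
    """

    label_image: np.ndarray
    threshold_er: int
    threshold_sheet: int
    source_pixel_size_nm: float | None = None
    strategy: str = "double_renyi"

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_image)
        if not np.isin(labels, [0, 1, 2]).all():
            raise FormatError("label image must contain only {0,1,2}")
        if self.threshold_sheet < self.threshold_er:
            raise FormatError("threshold_sheet must be >= threshold_er")
        self.label_image = labels.astype(np.uint8)

    @property
    def er_mask(self) -> np.ndarray:
        return self.label_image > LABEL_BACKGROUND

    @property
    def sheet_mask(self) -> np.ndarray:
        return self.label_image == LABEL_SHEET

    @property
    def tubule_mask(self) -> np.ndarray:
        return self.label_image == LABEL_TUBULE


def segment_er(
    image: np.ndarray,
    strategy: str = "double_renyi",
    threshold_mode: str = "three_alpha",
    alpha: float | None = None,
    width_cutoff_px: float = 4.0,
    min_object_px: int = 8,
    pixel_size_nm: float | None = None,
) -> ERSegmentation:
    """Segment an ER channel into background, tubules and sheets.

    A first Renyi threshold separates ER from background. Then either

    * ``double_renyi`` (default): a second Renyi threshold computed on the
      intensity histogram *within* the ER mask separates the brighter
      sheets from the dimmer tubules; or
    * ``renyi_plus_thickness``: ER structures that survive a morphological
      opening with a disk of diameter ``width_cutoff_px`` (i.e. locally
      wider than the cutoff) become sheet, the rest tubule.

    ``min_object_px`` is the usual particle-size cleanup applied after
    thresholding: connected ER components below this size are discarded as
    noise specks, and sheet fragments below it revert to tubule (both at
    8-connectivity). Every resolvable ER structure spans far more pixels
    than this at typical confocal sampling; set 0 to disable.
    """
    img8 = image if (np.asarray(image).dtype == np.uint8) else to_8bit(image)
    t_er = renyi_threshold(img8, mode=threshold_mode, alpha=alpha)
    er = img8 > t_er
    if min_object_px > 1:
        er = remove_small_objects(er, max_size=min_object_px - 1, connectivity=2)
    if not er.any():
        raise SegmentationError(f"empty ER mask at threshold {t_er}")

    if strategy == "double_renyi":
        hist = np.bincount(img8[er].ravel(), minlength=256).astype(float)
        if np.count_nonzero(hist) < 2:
            t_sheet = 255  # single ER intensity: everything is tubule
            sheet = np.zeros_like(er)
        else:
            t_sheet = max(renyi_threshold(hist, mode=threshold_mode, alpha=alpha), t_er)
            sheet = er & (img8 > t_sheet)
            # a threshold always splits the ER histogram, even a unimodal
            # one; accept the sheet class only if the split sits in a real
            # valley: the smoothed histogram between the threshold and the
            # sheet mode must dip well below both class peaks
            if sheet.any() and not _is_bimodal_split(hist, t_sheet):
                sheet = np.zeros_like(er)
                t_sheet = 255
    elif strategy == "renyi_plus_thickness":
        # local half-width from the Euclidean distance transform: pixels
        # deeper than width_cutoff/2 seed sheet regions, grown back out to
        # cover their structures
        from scipy import ndimage as _ndi

        edt = _ndi.distance_transform_edt(er)
        seeds = edt > width_cutoff_px / 2.0
        grow = max(int(math.ceil(width_cutoff_px / 2.0)), 1)
        sheet = _ndi.binary_dilation(seeds, disk(grow)) & er
        t_sheet = t_er
    else:
        raise DomainError(f"unknown segmentation strategy {strategy!r}")
    if min_object_px > 1:
        sheet = remove_small_objects(sheet, max_size=min_object_px - 1, connectivity=2)

    labels = np.zeros(img8.shape, dtype=np.uint8)
    labels[er] = LABEL_TUBULE
    labels[sheet] = LABEL_SHEET
    return ERSegmentation(labels, int(t_er), int(t_sheet), pixel_size_nm, strategy)


@dataclass
class LineSegmentProfile:
    """Sheet percentage along one radial band from the nuclear envelope.

    ``sheet_percentage = 100 * sheet_pixels / er_pixels`` within the band;
    NaN when the band contains no ER pixels.
    """

    segment_index: int
    width_px: int
    direction_deg: float
    start_rc: tuple[float, float]
    end_rc: tuple[float, float]
    sheet_pixels: int
    er_pixels: int
    sheet_percentage: float = field(init=False)

    def __post_init__(self) -> None:
        self.sheet_percentage = (
            100.0 * self.sheet_pixels / self.er_pixels
            if self.er_pixels > 0
            else float("nan")
        )


def _principal_axis_angle(mask: np.ndarray) -> float:
    """Angle (deg, from vertical/row axis, CCW toward columns) of the mask's
    principal axis, from second moments."""
    r, c = np.nonzero(mask)
    r = r - r.mean()
    c = c - c.mean()
    cov = np.array([[np.mean(r * r), np.mean(r * c)], [np.mean(r * c), np.mean(c * c)]])
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]  # (dr, dc) of major axis
    return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)


def sample_line_segments(
    seg: ERSegmentation,
    nucleus_mask: np.ndarray,
    directions: str | list[float] = "auto",
    width_px: int = 56,
    cell_mask: np.ndarray | None = None,
) -> list[LineSegmentProfile]:
    """Three radial bands from the nuclear envelope to the cell periphery.

    Each band is the rectangle of the given width starting at the nuclear
    boundary along its direction and extending to the cell-mask boundary
    (or the image edge). Directions are degrees measured from vertical
    (row axis, 0 = up the image) turning toward columns; ``"auto"`` places
    them at 120-degree spacing starting from the cell's long axis.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise DomainError("nucleus mask is empty")
    labels = seg.label_image
    if nucleus_mask.shape != labels.shape:
        raise FormatError("nucleus mask shape differs from segmentation")
    rr, cc = np.nonzero(nucleus_mask)
    if rr.min() == 0 or cc.min() == 0 or rr.max() == labels.shape[0] - 1 or (
        cc.max() == labels.shape[1] - 1
    ):
        raise DomainError("nucleus mask must be interior to the image")

    if directions == "auto":
        axis_mask = cell_mask if cell_mask is not None else seg.er_mask
        base = _principal_axis_angle(axis_mask)
        angles = [base, base + 120.0, base + 240.0]
    else:
        angles = list(directions)
        if len(angles) != 3:
            raise DomainError("exactly three segment directions are required")

    center = np.array([rr.mean(), cc.mean()])
    R, C = np.indices(labels.shape)
    rel_r, rel_c = R - center[0], C - center[1]
    inside = cell_mask.astype(bool) if cell_mask is not None else np.ones_like(
        nucleus_mask
    )

    profiles = []
    for idx, ang in enumerate(angles, start=1):
        a = np.deg2rad(ang)
        u = np.array([-np.cos(a), np.sin(a)])  # unit vector, 0 deg = "up"
        # march from the centroid to find the nuclear boundary and the
        # far end (cell boundary or image edge) along u
        s_nuc, s_end = 0.0, 0.0
        step = 0.5
        pos = center.copy()
        while True:
            pos = center + u * (s_end + step)
            ir, ic = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= ir < labels.shape[0] and 0 <= ic < labels.shape[1]):
                break
            if cell_mask is not None and not inside[ir, ic]:
                break
            s_end += step
            if nucleus_mask[ir, ic]:
                s_nuc = s_end
        proj = rel_r * u[0] + rel_c * u[1]
        perp = rel_r * u[1] - rel_c * u[0]
        band = (
            (proj >= s_nuc)
            & (proj <= s_end)
            & (np.abs(perp) <= width_px / 2.0)
            & ~nucleus_mask
            & inside
        )
        er_px = int(np.count_nonzero(band & seg.er_mask))
        sheet_px = int(np.count_nonzero(band & seg.sheet_mask))
        if er_px == 0:
            logger.warning("segment %d along %.1f deg contains no ER pixels", idx, ang)
        start = tuple(center + u * s_nuc)
        end = tuple(center + u * s_end)
        profiles.append(
            LineSegmentProfile(idx, width_px, float(ang % 360), start, end, sheet_px, er_px)
        )
    return profiles


def er_area_fraction(seg: ERSegmentation, cytoplasm_mask: np.ndarray) -> float:
    """Total ER area normalised by the cytoplasm area examined."""
    cyto = np.asarray(cytoplasm_mask, dtype=bool)
    if not cyto.any():
        raise DomainError("cytoplasm mask is empty")
    if cyto.shape != seg.label_image.shape:
        raise FormatError("cytoplasm mask shape differs from segmentation")
    return float(np.count_nonzero(seg.er_mask & cyto) / np.count_nonzero(cyto))
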