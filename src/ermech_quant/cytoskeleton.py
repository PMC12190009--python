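"""F-actin organisation: long-axis alignment, orientation, dispersion.

Orientation is *axial* data: a fiber at angle theta is the same fiber at
theta + 180 degrees, so all statistics operate on doubled angles. The
display convention is the one used for color-coded orientation maps:
images are first rotated so the cell's long axis is vertical, 0 degrees
means vertical and 90 degrees horizontal, with the axial fold
``min(phi, 180 - phi)`` mapping every orientation into [0, 90].

The per-pixel estimator is the structure tensor: the smoothed outer
product of intensity gradients, whose minor eigenvector points along the
local texture and whose eigenvalue contrast (lambda_max - lambda_min) /
(lambda_max + lambda_min) gives a 0..1 coherence weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor

from .errors import DegenerateInputError, DomainError

#: dispersion of a perfectly uniform axial distribution (degrees); the
#: angular deviation sqrt(2*(1-R)) of doubled angles at R=0, halved back
#: to the fiber-angle scale
MAX_DISPERSION_DEG = math.degrees(0.5 * math.sqrt(2.0))


@dataclass
class OrientationField:
    """Per-pixel fiber orientation and coherence.

    ``orientation_image`` holds the unfolded axial angle in [0, 180)
    degrees from vertical (used for circular statistics);
    ``angle_image`` is the folded display angle in [0, 90]. Both are NaN
    outside the analysis mask.
    """

    orientation_image: np.ndarray
    coherence_image: np.ndarray
    mask: np.ndarray
    tensor_sigma_px: float

    @property
    def angle_image(self) -> np.ndarray:
        a = self.orientation_image
        return np.where(a <= 90.0, a, 180.0 - a)


def _mask_principal_axis(mask: np.ndarray) -> tuple[float, float]:
    """(angle_from_vertical_deg, axis_ratio) of a binary mask."""
    r, c = np.nonzero(mask)
    r = r - r.mean()
    c = c - c.mean()
    cov = np.array(
        [[np.mean(r * r), np.mean(r * c)], [np.mean(r * c), np.mean(c * c)]]
    )
    vals, vecs = np.linalg.eigh(cov)
    ratio = math.sqrt(vals[1] / vals[0]) if vals[0] > 0 else math.inf
    v = vecs[:, 1]  # major axis (dr, dc)
    ang = math.degrees(math.atan2(v[1], v[0]))
    # fold to (-90, 90]: angle of the major axis measured from vertical
    if ang > 90:
        ang -= 180
    elif ang <= -90:
        ang += 180
    return ang, ratio


def align_long_axis(
    image: np.ndarray,
    cell_mask: np.ndarray,
    min_axis_ratio: float = 1.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate image and mask so the cell's long axis is vertical.

    The principal axis comes from the mask's second moments. Returns
    ``(rotated_image, rotated_mask, rotation_angle_deg)`` where the angle
    is the long axis' original inclination from vertical. A near-isotropic
    mask (axis ratio below ``min_axis_ratio``) has no defined long axis and
    raises :class:`DegenerateInputError`; pass an explicit angle-free
    analysis instead.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise DomainError("cell mask is empty")
    ang, ratio = _mask_principal_axis(cell_mask)
    if ratio < min_axis_ratio:
        raise DegenerateInputError(
            f"mask axis ratio {ratio:.3f} < {min_axis_ratio}: no long axis; "
            "rotate manually with a chosen angle"
        )
    # scipy rotates CCW in array (row, col) view for positive angles;
    # rotating by -ang maps the major axis onto the row (vertical) axis
    rot_img = ndimage.rotate(np.asarray(image, float), -ang, reshape=True, order=1)
    rot_mask = (
        ndimage.rotate(cell_mask.astype(float), -ang, reshape=True, order=0) > 0.5
    )
    return rot_img, rot_mask, float(ang)


def orientation_field(
    image: np.ndarray,
    mask: np.ndarray,
    tensor_sigma_px: float = 2.0,
) -> OrientationField:
    """Per-pixel axial orientation from the smoothed structure tensor."""
    if tensor_sigma_px <= 0:
        raise DomainError("tensor_sigma must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DomainError("analysis mask is empty")
    img = np.asarray(image, dtype=float)
    Jrr, Jrc, Jcc = structure_tensor(img, sigma=tensor_sigma_px, order="rc")
    # minor eigenvector (texture direction) of [[Jrr, Jrc], [Jrc, Jcc]]
    lam_min = 0.5 * ((Jrr + Jcc) - np.sqrt((Jrr - Jcc) ** 2 + 4 * Jrc**2))
    lam_max = (Jrr + Jcc) - lam_min
    vr = np.where(np.abs(Jrc) > 1e-30, Jrc, np.where(Jrr <= Jcc, 1.0, 0.0))
    vc = np.where(np.abs(Jrc) > 1e-30, lam_min - Jrr, np.where(Jrr <= Jcc, 0.0, 1.0))
    orient = np.degrees(np.arctan2(vc, vr)) % 180.0  # from vertical, [0,180)
    denom = lam_max + lam_min
    coher = np.where(denom > 1e-30, (lam_max - lam_min) / np.where(denom > 0, denom, 1.0), 0.0)
    orient = np.where(mask, orient, np.nan)
    coher = np.where(mask, np.clip(coher, 0.0, 1.0), np.nan)
    return OrientationField(orient, coher, mask, float(tensor_sigma_px))


def axial_dispersion(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular SD of doubled axial angles, on the fiber-angle scale.

    With resultant length R of the doubled angles, dispersion is the
    angular deviation ``sqrt(2 * (1 - R))`` halved back to fiber angles and
    expressed in degrees: 0 for perfectly parallel fibers, rising to
    :data:`MAX_DISPERSION_DEG` (~40.5 deg) for a uniform axial distribution.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float)) * 2.0
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape:
        raise DomainError("weights must match angles in shape")
    wsum = w.sum()
    if wsum <= 0:
        raise DomainError("weights sum to zero")
    R = math.hypot(float(np.sum(w * np.cos(a))), float(np.sum(w * np.sin(a)))) / wsum
    R = min(R, 1.0)
    return math.degrees(0.5 * math.sqrt(2.0 * (1.0 - R)))


def dispersion(
    field: OrientationField,
    mask: np.ndarray | None = None,
    weighting: str = "coherence",
    intensity_image: np.ndarray | None = None,
    min_pixels: int = 100,
) -> float:
    """Orientation dispersion of a field under the chosen pixel weighting."""
    m = field.mask if mask is None else (np.asarray(mask, bool) & field.mask)
    n = int(np.count_nonzero(m))
    if n < min_pixels:
        raise DomainError(f"only {n} masked pixels; need at least {min_pixels}")
    angles = field.orientation_image[m]
    if weighting == "coherence":
        w = field.coherence_image[m]
    elif weighting == "intensity":
        if intensity_image is None:
            raise DomainError("intensity weighting requires intensity_image")
        w = np.asarray(intensity_image, float)[m]
        if not np.any(w > 0):
            raise DomainError("intensity weights are all zero")
    elif weighting == "none":
        w = None
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return axial_dispersion(angles, w)


def intensity_density(
    image: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_nm: float | None = None,
) -> dict[str, float]:
    """Fluorescence intensity divided by cell area.

    Returns per-pixel density always, plus per-square-micrometre density
    when a pixel size is supplied.
    """
    m = np.asarray(cell_mask, dtype=bool)
    if not m.any():
        raise DomainError("cell mask is empty")
    img = np.asarray(image, dtype=float)
    per_px = float(img[m].sum() / np.count_nonzero(m))
    out = {"per_px": per_px}
    if pixel_size_nm is not None:
        px_area_um2 = (pixel_size_nm / 1000.0) ** 2
        out["per_um2"] = per_px / px_area_um2
    return out
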