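"""Organelle-organelle relationships: colocalization and contact sites.

Four quantifications live here:

* thresholded Manders coefficients M1/M2 between two channels;
* ER distribution mapping onto a thresholded mitochondria mask;
* membrane contact-site extent from digitized membrane polylines, the
  TEM-style measurement: two membranes are "in contact" wherever their
  reciprocal distance stays within a cutoff (30 nm for ER-mitochondria and
  PM-ER sections; the split-GFP sensor reports ~40 nm), and a site's
  extent is the arc length of a maximal contact run;
* 3D puncta counting for split-GFP contact-site sensors (threshold,
  size-filter, connected components).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import DomainError, FormatError, SegmentationError

ORGANELLE_LABELS = ("PM", "ER", "mitochondrion", "lysosome")


# --------------------------------------------------------------------------
# Manders colocalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocResult:
    """Thresholded Manders coefficients between two channels.

    M1 is the fraction of channel-1 signal lying over above-threshold
    channel-2 pixels; M2 the converse. Swapping the channels exchanges
    (M1, M2) exactly.
    """

    M1: float
    M2: float
    threshold_method: str
    threshold_ch1: float
    threshold_ch2: float

    def __post_init__(self) -> None:
        for m in (self.M1, self.M2):
            if not (0.0 <= m <= 1.0):
                raise DomainError("Manders coefficients must lie in [0, 1]")


def _channel_threshold(ch: np.ndarray, method: str, fixed: float | None) -> float:
    if method == "otsu":
        return float(threshold_otsu(ch))
    if method == "zero":
        return 0.0
    if method == "fixed":
        if fixed is None:
            raise DomainError("fixed threshold method requires a level")
        return float(fixed)
    raise DomainError(f"unknown threshold method {method!r}")


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    threshold_method: str = "otsu",
    thresholds: tuple[float, float] | None = None,
) -> ColocResult:
    """Thresholded Manders colocalization coefficients M1 and M2."""
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise FormatError("channels must share one shape")
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("intensities must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise DomainError("a channel is entirely zero; Manders is undefined")
    f1 = thresholds[0] if thresholds else None
    f2 = thresholds[1] if thresholds else None
    t1 = _channel_threshold(a, threshold_method, f1)
    t2 = _channel_threshold(b, threshold_method, f2)
    M1 = float(a[b > t2].sum() / a.sum())
    M2 = float(b[a > t1].sum() / b.sum())
    return ColocResult(M1, M2, threshold_method, t1, t2)


def er_on_mito_map(
    er_image: np.ndarray,
    mito_image: np.ndarray,
    mito_threshold_method: str = "otsu",
    mito_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Map normalised ER intensity onto the thresholded mitochondria mask.

    The mitochondria channel is segmented by its threshold; ER intensities
    are normalised to the per-image ER maximum and sampled on the
    mitochondria mask (NaN elsewhere). The scalar summary is the mean
    normalised ER intensity over the mask, in [0, 1].
    """
    er = np.asarray(er_image, dtype=float)
    mito = np.asarray(mito_image, dtype=float)
    if er.shape != mito.shape:
        raise FormatError("ER and mitochondria images must share one shape")
    t = _channel_threshold(mito, mito_threshold_method, mito_threshold)
    mask = mito > t
    if not mask.any():
        raise SegmentationError("mitochondria mask is empty at the threshold")
    if er.max() <= 0:
        raise DomainError("ER channel has no signal to normalise")
    er_norm = er / er.max()
    mapped = np.where(mask, er_norm, np.nan)
    return mapped, float(np.nanmean(mapped))


# --------------------------------------------------------------------------
# Membrane traces and contact extent
# --------------------------------------------------------------------------

@dataclass
class MembraneTrace:
    """Digitized membrane polyline in nm, with an organelle label."""

    points: np.ndarray  # (N, 2) [x_nm, y_nm]
    organelle: str
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise DomainError("a membrane trace needs at least 2 planar points")
        if self.organelle not in ORGANELLE_LABELS:
            raise DomainError(
                f"organelle must be one of {ORGANELLE_LABELS}, got {self.organelle!r}"
            )
        self.points = pts

    @property
    def segment_lengths_nm(self) -> np.ndarray:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    @property
    def arc_length_nm(self) -> float:
        return float(self.segment_lengths_nm.sum())

    def densified(self, max_spacing_nm: float = 1.0) -> "MembraneTrace":
        """Resample so consecutive points are at most ``max_spacing_nm`` apart."""
        if max_spacing_nm <= 0:
            raise DomainError("max_spacing must be positive")
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        out = [pts[0]]
        for p, q in zip(pts[:-1], pts[1:]):
            d = float(np.linalg.norm(q - p))
            n = max(int(np.ceil(d / max_spacing_nm)), 1)
            for k in range(1, n + 1):
                out.append(p + (q - p) * (k / n))
        pts_new = np.asarray(out)
        if self.closed:
            pts_new = pts_new[:-1]
        return MembraneTrace(pts_new, self.organelle, self.closed)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "organelle": self.organelle,
                "closed": self.closed,
                "points_nm": self.points.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MembraneTrace":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(np.asarray(d["points_nm"]), d["organelle"], d.get("closed", False))


@dataclass(frozen=True)
class ContactSite:
    """One maximal run of reciprocal membrane contact.

    ``extent_nm`` is the arc length along partner_a over which the gap to
    partner_b stays within ``max_gap_nm``.
    """

    partner_a: str
    partner_b: str
    extent_nm: float
    mean_gap_nm: float
    max_gap_nm: float

    def __post_init__(self) -> None:
        if self.extent_nm < 0:
            raise DomainError("extent must be non-negative")
        if self.mean_gap_nm > self.max_gap_nm + 1e-9:
            raise DomainError("mean gap cannot exceed the gating distance")


def contact_extent(
    trace_a: MembraneTrace,
    trace_b: MembraneTrace,
    max_gap_nm: float = 30.0,
    min_run_nm: float = 10.0,
    spacing_nm: float = 1.0,
    reciprocal: bool = True,
) -> list[ContactSite]:
    """Distance-gated contact sites between two membrane traces.

    Both traces are densified to at most ``spacing_nm`` point spacing; the
    gap at each point of ``trace_a`` is its distance to the nearest sampled
    point of ``trace_b``. Maximal runs of consecutive points with gap <=
    ``max_gap_nm`` whose arc length reaches ``min_run_nm`` become contact
    sites. With ``reciprocal=True`` (the default reading of a "reciprocal
    distance") a point only counts when its nearest partner point is
    itself within the cutoff of ``trace_a`` — one-sided overhangs cannot
    inflate the extent. Runs separated by out-of-cutoff stretches remain
    distinct sites.
    """
    if max_gap_nm <= 0 or min_run_nm < 0:
        raise DomainError("max_gap must be positive and min_run non-negative")
    a = trace_a.densified(spacing_nm)
    b = trace_b.densified(spacing_nm)
    tree_b = cKDTree(b.points)
    gap_a, idx_near = tree_b.query(a.points)
    contact = gap_a <= max_gap_nm
    if reciprocal:
        gap_b, _ = cKDTree(a.points).query(b.points)
        contact &= (gap_b <= max_gap_nm)[idx_near]

    steps = a.segment_lengths_nm  # length between point i and i+1
    sites: list[ContactSite] = []
    i, n = 0, contact.size
    while i < n:
        if not contact[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and contact[j + 1]:
            j += 1
        extent = float(steps[i:j].sum())
        if extent >= min_run_nm:
            sites.append(
                ContactSite(
                    trace_a.organelle,
                    trace_b.organelle,
                    extent,
                    float(gap_a[i : j + 1].mean()),
                    float(max_gap_nm),
                )
            )
        i = j + 1
    return sites


def total_contact_extent(sites: list[ContactSite]) -> float:
    return float(sum(s.extent_nm for s in sites))


def classify_cortical_er(
    lumen_widths_nm: np.ndarray,
    thin_cutoff_nm: float = 30.0,
) -> tuple[list[str], dict[str, float]]:
    """Split cortical-ER segments into thin vs wide lumen classes.

    Widths below the cutoff are "thin"; widths at or above it are "wide"
    (boundary convention: the cutoff itself is wide). Returns per-segment
    labels and the class proportions.
    """
    w = np.asarray(lumen_widths_nm, dtype=float)
    if w.size == 0:
        raise DomainError("no cortical-ER segments supplied")
    if np.any(w <= 0):
        raise DomainError("lumen widths must be positive")
    labels = ["thin" if x < thin_cutoff_nm else "wide" for x in w]
    n = len(labels)
    props = {
        "thin": labels.count("thin") / n,
        "wide": labels.count("wide") / n,
    }
    return labels, props


# --------------------------------------------------------------------------
# SPLICS puncta counting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctaCount:
    """Connected-component count of a thresholded 3D sensor volume."""

    count: int
    voxel_threshold: float
    min_voxels: int
    connectivity: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DomainError("count must be non-negative")
        if self.connectivity not in (6, 26):
            raise DomainError("connectivity must be 6 or 26")


def count_splics_puncta(
    zstack: np.ndarray,
    threshold_method: str = "otsu",
    threshold: float | None = None,
    min_voxels: int = 4,
    connectivity: int = 26,
) -> PunctaCount:
    """Count split-GFP contact-site puncta in a 3D stack.

    Threshold the stack, drop components smaller than ``min_voxels``, and
    count connected components under 6- (face) or 26- (face+edge+corner)
    connectivity. A stack that is blank after thresholding yields count 0.
    """
    vol = np.asarray(zstack, dtype=float)
    if vol.ndim != 3:
        raise FormatError("puncta counting expects a 3D z-stack")
    if connectivity not in (6, 26):
        raise DomainError("connectivity must be 6 or 26")
    if vol.max() <= vol.min():
        return PunctaCount(0, float(vol.max()), min_voxels, connectivity)
    t = _channel_threshold(vol, threshold_method, threshold)
    binary = vol > t
    skimage_conn = 1 if connectivity == 6 else 3
    if min_voxels > 1:
        binary = remove_small_objects(binary, max_size=min_voxels - 1, connectivity=skimage_conn)
    structure = ndimage.generate_binary_structure(3, skimage_conn)
    _, n = ndimage.label(binary, structure=structure)
    return PunctaCount(int(n), float(t), int(min_voxels), int(connectivity))
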