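"""Synthetic fixtures with ground truth for every pipeline input modality.

Each generator is a pure function of (parameters, seed): regenerating with
the same arguments reproduces the fixture bit-for-bit. Every generator
returns, alongside its fixture, a :class:`~ermech_quant.core.SyntheticTruth`
recording all parameters (units in key names) and the seed, which serves as
the oracle for recovery tests downstream.

All randomness flows through one ``numpy.random.default_rng(seed)``
generator per call; there is no global random state.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line_aa

from .assays import SoceTrace
from .core import CellImage, SyntheticTruth
from .er_morph import ERSegmentation, LABEL_SHEET, LABEL_TUBULE
from .errors import ConfigurationError, DomainError, GenerationError
from .flim import DecayHistogram
from .interactions import MembraneTrace


def strain_to_displacement(length_um: float, strain_pct: float) -> float:
    """Uniaxial displacement (um) that imposes ``strain_pct`` on a domain
    of ``length_um``: exactly ``length * strain / 100``.

    E.g. a 9% strain on a 60-um membrane-tethered domain corresponds to a
    5.4-um displacement.
    """
    if length_um <= 0:
        raise DomainError("length must be positive")
    if strain_pct < 0:
        raise DomainError("strain must be non-negative")
    return length_um * strain_pct / 100.0


# --------------------------------------------------------------------------
# TCSPC decay histograms
# --------------------------------------------------------------------------

def expected_decay_counts(
    tau1_ns: float,
    tau2_ns: float,
    frac1: float,
    n_photons: float,
    bin_width_ns: float = 0.05,
    n_bins: int = 250,
    background_frac: float = 0.0,
) -> np.ndarray:
    """Exact per-bin expected counts of the two-exponential mixture.

    ``frac1`` is the fraction of signal *photons* in the tau1 component
    (the arrival-time density is ``frac1/tau1 e^{-t/tau1} + ...``), so the
    pre-truncation mixture mean arrival time is
    ``frac1*tau1 + (1-frac1)*tau2``. Signal photons falling beyond the
    histogram window are truncated (not re-normalised); background photons
    are uniform over the window.
    """
    edges = np.arange(n_bins + 1) * bin_width_ns
    sig = n_photons * (1.0 - background_frac)

    def comp(tau: float) -> np.ndarray:
        cdf = 1.0 - np.exp(-edges / tau)
        return np.diff(cdf)

    mu = sig * (frac1 * comp(tau1_ns) + (1 - frac1) * comp(tau2_ns))
    mu += n_photons * background_frac / n_bins
    return mu


def gen_decay_histogram(
    tau1_ns: float,
    tau2_ns: float,
    frac1: float,
    n_photons: int,
    bin_width_ns: float = 0.05,
    n_bins: int = 250,
    background_frac: float = 0.0,
    irf_sigma_ns: float = 0.0,
    seed: int = 0,
) -> tuple[DecayHistogram, SyntheticTruth]:
    """Simulate a Poisson-counting TCSPC histogram of a biexponential decay.

    The total number of detected photons is Poisson with mean
    ``n_photons``; each signal photon's arrival is exponential with
    lifetime tau1 (probability ``frac1``) or tau2, optionally jittered by
    a Gaussian instrument response of width ``irf_sigma_ns``; background
    photons arrive uniformly in the window. Arrivals outside the window
    ``[0, n_bins * bin_width_ns)`` are truncated; the realised truncation
    fraction is recorded in the truth.
    """
    if not (tau1_ns > tau2_ns > 0):
        raise DomainError("component ordering requires tau1 > tau2 > 0")
    if not (0.0 < frac1 <= 1.0):
        raise DomainError("frac1 must lie in (0, 1]")
    if n_photons < 1:
        raise DomainError("n_photons must be at least 1")
    if not (0.0 <= background_frac < 1.0):
        raise DomainError("background_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    window = n_bins * bin_width_ns
    n_total = rng.poisson(n_photons)
    n_bg = rng.binomial(n_total, background_frac) if background_frac > 0 else 0
    n_sig = n_total - n_bg
    n1 = rng.binomial(n_sig, frac1)
    times = np.concatenate(
        [rng.exponential(tau1_ns, n1), rng.exponential(tau2_ns, n_sig - n1)]
    )
    if irf_sigma_ns > 0:
        times = times + rng.normal(0.0, irf_sigma_ns, times.size)
    kept = times[(times >= 0) & (times < window)]
    truncation_fraction = 1.0 - kept.size / n_sig if n_sig > 0 else 0.0
    bg_times = rng.uniform(0.0, window, n_bg)
    edges = np.arange(n_bins + 1) * bin_width_ns
    counts, _ = np.histogram(np.concatenate([kept, bg_times]), bins=edges)
    truth = SyntheticTruth(
        "gen_decay_histogram",
        {
            "tau1_ns": tau1_ns,
            "tau2_ns": tau2_ns,
            "frac1": frac1,
            "n_photons": n_photons,
            "bin_width_ns": bin_width_ns,
            "n_bins": n_bins,
            "background_frac": background_frac,
            "irf_sigma_ns": irf_sigma_ns,
            "truncation_fraction": truncation_fraction,
            "mean_arrival_ns_pretruncation": frac1 * tau1_ns + (1 - frac1) * tau2_ns,
        },
        seed,
    )
    return DecayHistogram(edges, counts), truth


# --------------------------------------------------------------------------
# ER cell images
# --------------------------------------------------------------------------

def _van_der_corput(k: int) -> float:
    """Base-2 radical inverse of k, a low-discrepancy sequence on (0, 1)."""
    v, denom = 0.0, 1.0
    while k:
        denom *= 2.0
        k, rem = divmod(k, 2)
        v += rem / denom
    return v

def gen_er_cell_image(
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_nm: float = 100.0,
    nucleus_radius_px: int = 60,
    n_tubules: int = 40,
    sheet_fraction_target: float = 0.3,
    intensity_levels: tuple[float, float, float] = (20.0, 100.0, 220.0),
    noise_sd: float = 8.0,
    sheet_placement: str = "perinuclear",
    seed: int = 0,
) -> tuple[CellImage, ERSegmentation, SyntheticTruth]:
    """Synthetic GFP-ER cell: nucleus, radiating tubules, sheet blobs.

    The cell is a disk; thin curvilinear tubules (1-3 px wide) radiate
    from the nuclear envelope to the periphery; compact sheet blobs are
    added (perinuclear by default, or radially ``"uniform"``) until the
    realised sheet fraction of ER pixels reaches ``sheet_fraction_target``.
    Pixel intensities take the three levels (background < tubule < sheet)
    plus Gaussian noise. The returned segmentation is the ground-truth
    label image; the realised sheet fraction is recorded in the truth.
    """
    bg_level, tub_level, sheet_level = intensity_levels
    if not (bg_level < tub_level < sheet_level):
        raise DomainError("intensity levels must be ordered background < tubule < sheet")
    if not (0.0 <= sheet_fraction_target <= 1.0):
        raise DomainError("sheet_fraction_target must lie in [0, 1]")
    if sheet_placement not in ("perinuclear", "uniform"):
        raise ConfigurationError(f"unknown sheet placement {sheet_placement!r}")
    ny, nx = image_shape
    center = (ny / 2.0, nx / 2.0)
    cell_radius = 0.45 * min(ny, nx)
    if nucleus_radius_px >= cell_radius:
        raise DomainError("nucleus larger than the cell/image")
    rng = np.random.default_rng(seed)

    nucleus = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_disk(center, nucleus_radius_px, shape=image_shape)
    nucleus[rr, cc] = True
    cell = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_disk(center, cell_radius, shape=image_shape)
    cell[rr, cc] = True
    cytoplasm = cell & ~nucleus

    tubule = np.zeros(image_shape, dtype=bool)
    for k in range(n_tubules):
        # stratified launch angles: real ER networks fill the cytoplasm
        # without the angular clumping of independent random directions
        ang = (k + rng.uniform(0.25, 0.75)) * 2 * math.pi / n_tubules
        half_width = rng.integers(0, 2)  # total width 1-3 px
        r = float(nucleus_radius_px) + 1.0
        pos = np.array(center) + r * np.array([math.sin(ang), math.cos(ang)])
        while True:
            step_ang = ang + rng.normal(0.0, 0.25)
            ang = 0.8 * ang + 0.2 * step_ang  # smooth curvature
            new = pos + 4.0 * np.array([math.sin(ang), math.cos(ang)])
            rr0, cc0 = line_aa(
                int(round(pos[0])), int(round(pos[1])),
                int(round(new[0])), int(round(new[1])),
            )[:2]
            ok = (rr0 >= 0) & (rr0 < ny) & (cc0 >= 0) & (cc0 < nx)
            for dr in range(-half_width, half_width + 1):
                rr1 = np.clip(rr0[ok] + dr, 0, ny - 1)
                tubule[rr1, cc0[ok]] = True
            pos = new
            if np.hypot(pos[0] - center[0], pos[1] - center[1]) >= cell_radius:
                break
    tubule &= cytoplasm

    sheet = np.zeros(image_shape, dtype=bool)
    if sheet_fraction_target > 0:
        if sheet_placement == "perinuclear":
            r_lo, r_hi = nucleus_radius_px + 5, (nucleus_radius_px + cell_radius) / 2
            blob_r_range = (6.0, 14.0)
        else:
            # radially uniform *fraction*: sheet density must track the
            # 1/r areal density of the radiating tubules, so blob centres
            # are uniform in radius and small enough that any radial band
            # samples the same sheet share
            r_lo, r_hi = nucleus_radius_px + 5, cell_radius - 5
            blob_r_range = (3.0, 3.0)
            # sheets belong to the same network as tubules: centre blobs on
            # tubule pixels, visiting angular quantiles of the tubule-pixel
            # distribution in bit-reversed order so every direction carries
            # the same sheet *share* of its local ER
            tub_r, tub_c = np.nonzero(tubule)
            tub_angle = np.arctan2(tub_r - center[0], tub_c - center[1])
            angular_order = np.argsort(tub_angle, kind="stable")
        for k in range(100000):
            er_px = np.count_nonzero(tubule | sheet)
            sheet_px = np.count_nonzero(sheet)
            if er_px > 0 and sheet_px / er_px >= sheet_fraction_target:
                break
            if sheet_placement == "uniform":
                j = angular_order[int(_van_der_corput(k + 1) * len(angular_order))]
                blob_c = (float(tub_r[j]), float(tub_c[j]))
            else:
                rad = rng.uniform(r_lo, r_hi)
                ang = rng.uniform(0, 2 * math.pi)
                blob_c = (
                    center[0] + rad * math.sin(ang),
                    center[1] + rad * math.cos(ang),
                )
            blob_r = rng.uniform(*blob_r_range)
            rr, cc = draw_disk(blob_c, blob_r, shape=image_shape)
            keep = cytoplasm[rr, cc]
            sheet[rr[keep], cc[keep]] = True
    tubule &= ~sheet

    labels = np.zeros(image_shape, dtype=np.uint8)
    labels[tubule] = LABEL_TUBULE
    labels[sheet] = LABEL_SHEET
    er_px = np.count_nonzero(labels > 0)
    realized_fraction = np.count_nonzero(sheet) / er_px if er_px else 0.0

    img = np.full(image_shape, bg_level, dtype=float)
    img[tubule] = tub_level
    img[sheet] = sheet_level
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, image_shape), 0.0, None)

    cell_image = CellImage(
        img[None],
        ["ER"],
        pixel_size_nm,
        masks={"nucleus": nucleus, "cell": cell, "cytoplasm": cytoplasm},
    )
    # nominal separating levels (midpoints between the generative levels)
    t_er = int((bg_level + tub_level) / 2)
    t_sheet = int((tub_level + sheet_level) / 2)
    truth_seg = ERSegmentation(labels, t_er, t_sheet, pixel_size_nm, "ground_truth")
    truth = SyntheticTruth(
        "gen_er_cell_image",
        {
            "image_shape_px": list(image_shape),
            "pixel_size_nm": pixel_size_nm,
            "nucleus_radius_px": nucleus_radius_px,
            "n_tubules": n_tubules,
            "sheet_fraction_target": sheet_fraction_target,
            "realized_sheet_fraction": realized_fraction,
            "intensity_levels_au": list(intensity_levels),
            "noise_sd_au": noise_sd,
            "sheet_placement": sheet_placement,
        },
        seed,
    )
    return cell_image, truth_seg, truth


# --------------------------------------------------------------------------
# Membrane trace pairs with prescribed gap profiles
# --------------------------------------------------------------------------

def _gap_function(gap_profile: dict):
    name = gap_profile.get("name")
    if name == "constant":
        g = float(gap_profile["gap_nm"])
        return lambda x: np.full_like(np.asarray(x, float), g)
    if name == "linear":
        g0, g1 = float(gap_profile["start_nm"]), float(gap_profile["end_nm"])
        span = float(gap_profile["_span_nm"])
        return lambda x: g0 + (g1 - g0) * np.asarray(x, float) / span
    if name == "sinusoid":
        a = float(gap_profile["mean_nm"])
        b = float(gap_profile["amplitude_nm"])
        period = float(gap_profile["period_nm"])
        phase = float(gap_profile.get("phase_rad", 0.0))
        return lambda x: a + b * np.sin(2 * np.pi * np.asarray(x, float) / period + phase)
    raise ConfigurationError(f"unknown gap profile {name!r}")


def analytic_contact_extent(
    gap_profile: dict, span_nm: float, cutoff_nm: float
) -> float:
    """Closed-form arc length of {x in [0, span]: gap(x) <= cutoff}.

    For the sinusoid the crossing points come from the analytic roots of
    ``sin(u) = (cutoff - mean)/amplitude`` enumerated over the span.
    """
    name = gap_profile.get("name")
    if name == "constant":
        return span_nm if gap_profile["gap_nm"] <= cutoff_nm else 0.0
    if name == "linear":
        g0, g1 = float(gap_profile["start_nm"]), float(gap_profile["end_nm"])
        if g0 == g1:
            return span_nm if g0 <= cutoff_nm else 0.0
        # gap(x) = g0 + (g1-g0) x / span <= cutoff
        xc = span_nm * (cutoff_nm - g0) / (g1 - g0)
        if g1 > g0:  # increasing: satisfied on [0, xc]
            return float(np.clip(xc, 0.0, span_nm))
        return float(span_nm - np.clip(xc, 0.0, span_nm))
    if name == "sinusoid":
        a = float(gap_profile["mean_nm"])
        b = float(gap_profile["amplitude_nm"])
        period = float(gap_profile["period_nm"])
        phase = float(gap_profile.get("phase_rad", 0.0))
        s = (cutoff_nm - a) / b if b != 0 else math.inf
        if s >= 1.0:
            return span_nm
        if s <= -1.0:
            return 0.0
        # measure of {u: sin u > s} per 2*pi period is pi - 2*arcsin(s);
        # enumerate the "above cutoff" intervals u in (asin(s)+2k pi,
        # pi - asin(s) + 2k pi) and subtract their overlap with the span
        u0, u1 = math.asin(s), math.pi - math.asin(s)
        ua, ub = phase, phase + 2 * math.pi * span_nm / period
        above = 0.0
        k = math.floor((ua - u1) / (2 * math.pi))
        while True:
            lo, hi = u0 + 2 * math.pi * k, u1 + 2 * math.pi * k
            if lo >= ub:
                break
            ov = max(0.0, min(hi, ub) - max(lo, ua))
            above += ov
            k += 1
        return span_nm - above * period / (2 * math.pi)
    raise ConfigurationError(f"unknown gap profile {name!r}")


def gen_membrane_pair(
    span_nm: float,
    sampling_step_nm: float,
    gap_profile: dict,
    cutoff_nm: float = 30.0,
    organelles: tuple[str, str] = ("ER", "mitochondrion"),
) -> tuple[MembraneTrace, MembraneTrace, float, SyntheticTruth]:
    """Paired membrane polylines whose pointwise vertical gap follows a
    named profile (constant / linear ramp / sinusoid).

    Trace A is straight along x at y=0; trace B sits at y=gap(x). The
    returned analytic extent is the closed-form arc length along A where
    gap(x) <= ``cutoff_nm``. Profiles are deterministic, so the truth seed
    is 0 by convention.
    """
    if sampling_step_nm <= 0:
        raise DomainError("sampling_step must be positive")
    if span_nm <= 0:
        raise DomainError("span must be positive")
    profile = dict(gap_profile)
    profile["_span_nm"] = span_nm
    g = _gap_function(profile)
    x = np.arange(0.0, span_nm + sampling_step_nm / 2, sampling_step_nm)
    a = MembraneTrace(np.column_stack([x, np.zeros_like(x)]), organelles[0])
    b = MembraneTrace(np.column_stack([x, g(x)]), organelles[1])
    extent = analytic_contact_extent(gap_profile, span_nm, cutoff_nm)
    truth = SyntheticTruth(
        "gen_membrane_pair",
        {
            "span_nm": span_nm,
            "sampling_step_nm": sampling_step_nm,
            "gap_profile": {k: v for k, v in gap_profile.items()},
            "cutoff_nm": cutoff_nm,
            "analytic_extent_nm": extent,
        },
        0,
    )
    return a, b, extent, truth


# --------------------------------------------------------------------------
# Oriented fiber images
# --------------------------------------------------------------------------

def gen_fiber_image(
    image_shape: tuple[int, int] = (256, 256),
    n_fibers: int = 30,
    mean_angle_deg: float = 0.0,
    concentration: float = 4.0,
    intensity: float = 200.0,
    fiber_sigma_px: float = 1.5,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[CellImage, np.ndarray, SyntheticTruth]:
    """Straight fibers with axial angles from a von Mises distribution.

    Angles follow the axial convention (0 deg = vertical, 90 deg =
    horizontal): each fiber's orientation is drawn by sampling a von Mises
    variate on *doubled* angles with mean ``2 * mean_angle_deg`` and
    concentration kappa, then halving (kappa=0 gives the uniform axial
    distribution; kappa=inf makes every fiber equal to the mean). Truth
    lists the fiber angles in degrees in [0, 180).

    Fibers are rendered analytically with a Gaussian cross-section of
    width ``fiber_sigma_px`` (no rasterised staircase), so the image
    carries the stated orientations without aliasing bias.
    """
    if n_fibers < 1:
        raise DomainError("n_fibers must be at least 1")
    if concentration < 0:
        raise DomainError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    if math.isinf(concentration):
        angles = np.full(n_fibers, mean_angle_deg % 180.0)
    else:
        doubled = rng.vonmises(np.deg2rad(2 * mean_angle_deg), concentration, n_fibers)
        angles = (np.degrees(doubled) / 2.0) % 180.0

    ny, nx = image_shape
    img = np.full(image_shape, 10.0)
    yy, xx = np.indices(image_shape, dtype=float)
    for ang in angles:
        a = math.radians(ang)
        # 0 deg = vertical: direction (d_row, d_col) = (cos a, sin a); a
        # fiber at 90 deg runs along columns (horizontal)
        normal = np.array([-math.sin(a), math.cos(a)])
        c = np.array([rng.uniform(0, ny), rng.uniform(0, nx)])
        d_perp = (yy - c[0]) * normal[0] + (xx - c[1]) * normal[1]
        profile = intensity * np.exp(-(d_perp**2) / (2.0 * fiber_sigma_px**2))
        img = np.maximum(img, profile)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, image_shape), 0.0, None)

    cell_image = CellImage(
        img[None], ["F-actin"], 100.0, masks={"cell": np.ones(image_shape, bool)}
    )
    truth = SyntheticTruth(
        "gen_fiber_image",
        {
            "image_shape_px": list(image_shape),
            "n_fibers": n_fibers,
            "mean_angle_deg": mean_angle_deg,
            "concentration_kappa": concentration,
            "intensity_au": intensity,
            "fiber_sigma_px": fiber_sigma_px,
            "noise_sd_au": noise_sd,
            "angles_deg": angles.tolist(),
        },
        seed,
    )
    return cell_image, angles, truth


# --------------------------------------------------------------------------
# 3D puncta volumes
# --------------------------------------------------------------------------

def gen_puncta_volume(
    stack_shape: tuple[int, int, int] = (32, 128, 128),
    n_puncta: int = 20,
    radius_px: float = 3.0,
    min_separation_px: float = 9.0,
    intensity: float = 200.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    max_attempts_per_punctum: int = 1000,
) -> tuple[CellImage, SyntheticTruth]:
    """Spherical puncta at centres kept ``min_separation_px`` apart.

    Rejection sampling places each centre at least the separation from all
    previous centres and at least ``radius + 1`` voxels from the borders;
    infeasible packings fail with a :class:`GenerationError` naming the
    constraint after a bounded number of attempts.
    """
    if n_puncta < 0:
        raise DomainError("n_puncta must be non-negative")
    rng = np.random.default_rng(seed)
    nz, ny, nx = stack_shape
    margin = radius_px + 1
    if n_puncta > 0 and (nz <= 2 * margin or ny <= 2 * margin or nx <= 2 * margin):
        raise GenerationError("stack too small for the requested punctum radius")
    centers: list[np.ndarray] = []
    for i in range(n_puncta):
        for _ in range(max_attempts_per_punctum):
            c = rng.uniform([margin] * 3, [nz - margin, ny - margin, nx - margin])
            if all(np.linalg.norm(c - p) >= min_separation_px for p in centers):
                centers.append(c)
                break
        else:
            raise GenerationError(
                f"could not place punctum {i + 1}/{n_puncta} with "
                f"min_separation {min_separation_px} px after "
                f"{max_attempts_per_punctum} attempts"
            )
    vol = np.zeros(stack_shape, dtype=float)
    zz, yy, xx = np.indices(stack_shape)
    for c in centers:
        m = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius_px**2
        vol[m] = intensity
    if noise_sd > 0:
        vol = np.clip(vol + rng.normal(0.0, noise_sd, stack_shape), 0.0, None)
    cell_image = CellImage(vol[None], ["SPLICS"], 100.0, z_step_nm=200.0)
    truth = SyntheticTruth(
        "gen_puncta_volume",
        {
            "stack_shape_px": list(stack_shape),
            "n_puncta": n_puncta,
            "radius_px": radius_px,
            "min_separation_px": min_separation_px,
            "intensity_au": intensity,
            "noise_sd_au": noise_sd,
            "centers_px": [c.tolist() for c in centers],
        },
        seed,
    )
    return cell_image, truth


# --------------------------------------------------------------------------
# SOCE traces
# --------------------------------------------------------------------------

#: protocol timing: 5-min Ca2+-free wash, 30-min store depletion, then
#: readdition; indicator read every 5 s
SOCE_PROTOCOL = {
    "ca_free_start_s": 0.0,
    "depletion_start_s": 300.0,
    "readdition_s": 2100.0,
    "post_readdition_s": 300.0,
    "sampling_interval_s": 5.0,
}


def gen_soce_trace(
    baseline_F: float = 1.0,
    peak_F: float = 3.0,
    rise_tau_s: float = 10.0,
    decay_tau_s: float = 90.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SoceTrace, SyntheticTruth]:
    """Ca2+-readdition (SOCE) trace following the standard protocol.

    The trace holds at ``baseline_F`` through the Ca2+-free wash and store
    depletion, then rises as a double-exponential transient
    ``exp(-t/decay_tau) - exp(-t/rise_tau)`` scaled so its maximum over
    the sampled grid equals ``peak_F`` exactly (hence noiseless recovery
    of the normalised maximum is exact).
    """
    if baseline_F <= 0:
        raise DomainError("baseline fluorescence must be positive")
    if peak_F < baseline_F:
        raise DomainError("peak must be at least the baseline")
    if rise_tau_s <= 0 or decay_tau_s <= rise_tau_s:
        raise DomainError("require decay_tau > rise_tau > 0")
    p = SOCE_PROTOCOL
    t_end = p["readdition_s"] + p["post_readdition_s"]
    t = np.arange(0.0, t_end + p["sampling_interval_s"] / 2, p["sampling_interval_s"])
    f = np.full_like(t, baseline_F)
    post = t >= p["readdition_s"]
    tp = t[post] - p["readdition_s"]
    shape = np.exp(-tp / decay_tau_s) - np.exp(-tp / rise_tau_s)
    if shape.max() > 0:
        f[post] = baseline_F + (peak_F - baseline_F) * shape / shape.max()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, f.size), 1e-9, None)
    marks = {k: p[k] for k in ("ca_free_start_s", "depletion_start_s", "readdition_s")}
    trace = SoceTrace(t, f, marks)
    truth = SyntheticTruth(
        "gen_soce_trace",
        {
            "baseline_F_au": baseline_F,
            "peak_F_au": peak_F,
            "rise_tau_s": rise_tau_s,
            "decay_tau_s": decay_tau_s,
            "noise_sd_au": noise_sd,
            "normalized_max_truth": peak_F / baseline_F,
            **{f"phase_{k}": v for k, v in marks.items()},
        },
        seed,
    )
    return trace, truth
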