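"""Confocal image quantification: the BCRI pixel-to-particle chain.

The plasma membrane is segmented on the reference (eGFP) channel with Otsu's
threshold and the largest connected component is kept. Within that mask,
photon counts are averaged, divided by the pixel dwell time to give a count
rate, divided by the molecular brightness (CPP) of the fluorophore to give a
particle number, and rescaled by 1/(1−p_nf) for the non-fluorescent label
fraction. Ratios between channels then yield click efficiency (CE) and
ligand occupancy; the reference particle number over the equatorial
cross-section A_eff gives the receptor surface density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label

from .calibration import FocalVolumeCalibration

__all__ = [
    "ChannelImage",
    "MembraneMask",
    "CellQuantification",
    "AVOGADRO",
    "segment_membrane",
    "register_channels",
    "pixels_to_particles",
    "quantify_cell",
    "rescale_ce_occupied",
    "concentration_from_particles",
]

AVOGADRO = 6.02214076e23  # mol⁻¹

#: Count rate above which photon-counting detectors saturate noticeably.
SATURATION_RATE_HZ = 1e6


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel photon-counting confocal image with acquisition metadata."""

    pixels: np.ndarray  # integer photon counts
    dwell_time: float  # s per pixel
    pixel_size: float  # µm
    channel: str = ""
    laser_line: float = 0.0  # nm
    P_tot: float = 0.0  # µW

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if np.any(px < 0):
            raise ValueError("photon counts must be non-negative")
        if self.dwell_time <= 0:
            raise ValueError("dwell time must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class MembraneMask:
    """Largest connected membrane component from threshold segmentation."""

    mask: np.ndarray  # bool
    component_area: int
    source_channel: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not m.any():
            raise ValueError("mask is empty")
        if int(m.sum()) != self.component_area:
            raise ValueError("component_area must equal the mask pixel count")


@dataclass
class CellQuantification:
    """Per-cell BCRI readout."""

    cell_id: str
    N_ref: float
    N_click: float
    N_ligand: float
    CE: float
    occupancy: float
    density: float  # receptors per µm²
    flags: list[str] = field(default_factory=list)


def segment_membrane(
    img: ChannelImage, smooth_sigma: float = 1.0, connectivity: int = 2
) -> MembraneMask:
    """Otsu-threshold the image and keep the largest connected component.

    A light Gaussian smoothing (``smooth_sigma`` in pixels, 0 disables it)
    stabilises the threshold on Poisson-noisy photon counts; the threshold is
    applied to the smoothed image but the mask refers to original pixels.
    8-connectivity (``connectivity=2``) joins diagonal membrane pixels.
    """
    px = img.pixels.astype(float)
    if px.max() == px.min():
        raise ValueError("constant image: no threshold exists")
    work = gaussian(px, sigma=smooth_sigma, preserve_range=True) if smooth_sigma > 0 else px
    thr = threshold_otsu(work)
    fg = work > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    lab = label(fg, connectivity=connectivity)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    biggest = int(counts.argmax())
    mask = lab == biggest
    return MembraneMask(
        mask=mask, component_area=int(mask.sum()), source_channel=img.channel
    )


def register_channels(
    ref_mask: np.ndarray,
    other: np.ndarray,
    max_shift: int = 2,
    tie_tolerance: float = 1e-3,
) -> tuple[tuple[int, int], float]:
    """Integer-pixel offset of ``other`` that best overlaps ``ref_mask``.

    Exhaustive search over shifts within ±``max_shift``; returns the shift
    (dy, dx) and the achieved overlap fraction (intersection over reference
    area). A shift is only adopted when it beats the unshifted overlap by
    more than ``tie_tolerance`` — chromatic displacement on the calibrated
    instrument is sub-pixel, so (0, 0) is the physically expected answer.
    """
    ref = np.asarray(ref_mask, dtype=bool)
    oth = np.asarray(other, dtype=bool)
    if ref.shape != oth.shape:
        raise ValueError("masks must share a shape")
    area = max(int(ref.sum()), 1)

    def overlap(dy: int, dx: int) -> float:
        shifted = np.roll(np.roll(oth, dy, axis=0), dx, axis=1)
        return float(np.logical_and(ref, shifted).sum()) / area

    base = overlap(0, 0)
    best = (0, 0)
    best_ov = base
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ov = overlap(dy, dx)
            if ov > best_ov + tie_tolerance:
                best, best_ov = (dy, dx), ov
    return best, best_ov


def pixels_to_particles(
    img: ChannelImage,
    mask: MembraneMask,
    cpp: float,
    p_nf: float = 0.0,
    background_rate: float = 0.0,
) -> float:
    """Convert masked photon counts into a corrected particle number.

    F = mean(counts in mask)/dwell_time (kHz), N_raw = F/CPP, and
    N = N_raw/(1−p_nf) corrects for non-fluorescent labels (immature
    fluorescent protein, unlabeled ligand). ``background_rate`` (kHz) is an
    optional constant offset subtracted from F before division.
    """
    if cpp <= 0:
        raise ValueError("CPP must be positive")
    if not (0 <= p_nf < 1):
        raise ValueError("p_nf must be in [0, 1)")
    m = mask.mask
    if m.shape != img.pixels.shape:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("empty mask")
    mean_counts = float(img.pixels[m].mean())
    f_khz = mean_counts / img.dwell_time / 1000.0  # counts/s → kHz
    f_khz = max(f_khz - background_rate, 0.0)
    n_raw = f_khz / cpp
    return n_raw / (1.0 - p_nf)


def saturated_fraction(img: ChannelImage, mask: MembraneMask | None = None) -> float:
    """Fraction of (masked) pixels whose instantaneous count rate exceeds 1 MHz."""
    px = img.pixels if mask is None else img.pixels[mask.mask]
    rate = px / img.dwell_time
    return float(np.mean(rate > SATURATION_RATE_HZ))


def quantify_cell(
    channels: dict[str, ChannelImage],
    calibrations: dict[str, FocalVolumeCalibration],
    cpp: dict[str, float],
    p_nf: dict[str, float] | None = None,
    reference: str = "egfp",
    click: str = "click",
    ligand: str = "ligand",
    cell_id: str = "cell",
    register: bool = False,
    interior_erosion: int = 1,
) -> CellQuantification:
    """Full BCRI quantification of one cell from its channel images.

    The membrane mask is derived from the reference channel and shared by all
    channels (optionally after integer registration). CE = N_click/N_ref,
    occupancy = N_ligand/N_ref, density = N_ref/A_eff of the reference line.
    Saturated pixels (>1 MHz instantaneous rate) are reported as a flag, not
    dropped.

    ``interior_erosion`` shrinks the shared mask by that many pixels before
    intensities are averaged: boundary pixels are dimmed by the point-spread
    function and would bias mean rates (hence absolute particle numbers)
    downward. Ratios between channels are insensitive to this choice. If
    erosion would empty the mask, the uneroded mask is used.
    """
    if reference not in channels:
        raise ValueError(f"reference channel '{reference}' missing")
    for name in channels:
        if name not in cpp:
            raise ValueError(f"no brightness (CPP) for channel '{name}'")
    line = channels[reference].laser_line
    if reference not in calibrations and line not in {
        c.laser_line for c in calibrations.values()
    }:
        raise ValueError("missing focal-volume calibration for the reference channel")
    p_nf = dict(p_nf or {})

    mask = segment_membrane(channels[reference])
    if interior_erosion > 0:
        from scipy.ndimage import binary_erosion

        eroded = binary_erosion(mask.mask, iterations=interior_erosion)
        if eroded.any():
            mask = MembraneMask(
                mask=eroded,
                component_area=int(eroded.sum()),
                source_channel=mask.source_channel,
            )
    flags: list[str] = []
    numbers: dict[str, float] = {}
    for name, img in channels.items():
        m = mask
        if register and name != reference:
            (dy, dx), _ = register_channels(mask.mask, segment_membrane(img).mask)
            if (dy, dx) != (0, 0):
                shifted = np.roll(np.roll(img.pixels, dy, axis=0), dx, axis=1)
                img = ChannelImage(
                    pixels=shifted,
                    dwell_time=img.dwell_time,
                    pixel_size=img.pixel_size,
                    channel=img.channel,
                    laser_line=img.laser_line,
                    P_tot=img.P_tot,
                )
        sat = saturated_fraction(img, m)
        if sat > 0:
            flags.append(f"{name}: {sat:.1%} pixels above 1 MHz")
        numbers[name] = pixels_to_particles(img, m, cpp[name], p_nf.get(name, 0.0))

    n_ref = numbers[reference]
    n_click = numbers.get(click, 0.0)
    n_ligand = numbers.get(ligand, 0.0)
    cal = calibrations.get(reference)
    if cal is None:
        cal = next(c for c in calibrations.values() if c.laser_line == line)
    ce = n_click / n_ref if n_ref > 0 else 0.0
    occ = n_ligand / n_ref if n_ref > 0 else 0.0
    return CellQuantification(
        cell_id=cell_id,
        N_ref=n_ref,
        N_click=n_click,
        N_ligand=n_ligand,
        CE=ce,
        occupancy=occ,
        density=n_ref / cal.A_eff,
        flags=flags,
    )


def rescale_ce_occupied(
    ce_occ_prime: float, ce_free: float, f_occ: float
) -> float:
    """Rescale a measured occupied-state CE for partial ligand occupancy.

    The measured CE'_occ of a partially occupied population is a linear mix
    of occupied and free states; inverting the mix with occupied fraction
    F_occ gives CE_occ = (CE'_occ − (1−F_occ)·CE_free)/F_occ.
    """
    if not (0 < f_occ <= 1):
        raise ValueError("F_occ must be in (0, 1]")
    return (ce_occ_prime - (1.0 - f_occ) * ce_free) / f_occ


def concentration_from_particles(n: float, v_eff: float) -> float:
    """Local concentration in mol/L from N particles in V_eff (µm³).

    c = N/(N_A·V_eff); 1 µm³ = 1e-15 L.
    """
    if v_eff <= 0:
        raise ValueError("V_eff must be positive")
    return n / (AVOGADRO * v_eff * 1e-15)
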