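"""Rebinning of masked 2D detector images on the (q_r, chi) grid.

Two one-dimensional reductions are supported:

* the radial profile ``I(q_r)`` — mean intensity per q bin, optionally
  restricted to azimuthal wedges (e.g. the region of a diffraction streak);
* the azimuthal profile ``H(chi)`` — the radial integral of the intensity
  over a fixed band ``[qmin, qmax]`` at each azimuth,
  ``H(chi) = int_{qmin}^{qmax} I(q_r, chi) dq_r``.

Pixels are assigned to bins whole (no pixel splitting), and bins that receive
no valid pixels are propagated as missing (NaN), never imputed as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .geometry import QChiMap

__all__ = [
    "DetectorImage",
    "RadialProfile",
    "AzimuthalProfile",
    "azimuthal_average",
    "radial_integrate",
    "fold_half_quadrant",
    "anisotropy_score",
    "subtract_isotropic_floor",
]

TWO_PI = 2.0 * math.pi


class ReductionError(ValueError):
    pass


@dataclass
class DetectorImage:
    """A photon-count image with a validity mask.

    ``mask`` is True on usable pixels; detector gaps, the beamstop shadow and
    dead modules are False.  Counts must be non-negative wherever the mask is
    True.
    """

    counts: np.ndarray
    mask: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ReductionError(f"counts must be 2D, got shape {self.counts.shape}")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.counts.shape:
            raise ReductionError(
                f"mask shape {self.mask.shape} != counts shape {self.counts.shape}"
            )
        if np.any(self.counts[self.mask] < 0):
            raise ReductionError("negative counts on unmasked pixels")


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs scattering-vector magnitude."""

    q_centers: np.ndarray
    q_edges: np.ndarray
    intensity: np.ndarray  # NaN where n_pixels == 0
    n_pixels: np.ndarray
    sector: list[tuple[float, float]] | None = None  # chi wedges (rad); None = full circle

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_pixels > 0


@dataclass
class AzimuthalProfile:
    """The streak profile H(chi): radial integral of I over [qmin, qmax].

    ``chi_centers`` holds the effective azimuth node of each bin — the
    contribution-weighted mean azimuth of the pixels that actually fed the
    bin.  On a coarse pixel grid the pixels of a narrow wedge cluster away
    from the nominal bin centre (whole pixel columns enter or leave the wedge
    near the principal axes), and evaluating downstream models at the
    effective nodes removes that quantization error.  For profiles built
    analytically the nodes are simply the requested chi grid.
    """

    chi_centers: np.ndarray
    H: np.ndarray  # intensity x nm^-1; NaN where the annulus sector is empty
    q_range: tuple[float, float] | None
    n_pixels: np.ndarray | None = None

    @property
    def nonempty(self) -> np.ndarray:
        return np.isfinite(self.H)


def _sector_mask(chi: np.ndarray, sector: Sequence[tuple[float, float]] | None) -> np.ndarray:
    """Boolean mask of pixels whose azimuth lies in any wedge of ``sector``.

    Wedges are (lo, hi) in radians and may wrap through zero (lo > hi).
    """
    if sector is None:
        return np.ones(chi.shape, dtype=bool)
    sector = list(sector)
    if not sector:
        raise ReductionError("sector of zero measure")
    sel = np.zeros(chi.shape, dtype=bool)
    total = 0.0
    for lo, hi in sector:
        width = (hi - lo) % TWO_PI
        if width == 0.0:
            continue
        total += width
        sel |= ((chi - lo) % TWO_PI) <= width
    if total == 0.0:
        raise ReductionError("sector of zero measure")
    return sel


def azimuthal_average(
    image: DetectorImage,
    qmap: QChiMap,
    q_edges: np.ndarray,
    sector: Sequence[tuple[float, float]] | None = None,
) -> RadialProfile:
    """Mean intensity per q bin over masked pixels inside the chi sector."""
    q_edges = np.asarray(q_edges, dtype=float)
    if q_edges.ndim != 1 or len(q_edges) < 2 or np.any(np.diff(q_edges) <= 0):
        raise ReductionError("q_edges must be a strictly increasing 1D sequence")
    usable = image.mask & qmap.valid
    if not usable.any():
        raise ReductionError("image is fully masked")
    sel = usable & _sector_mask(qmap.chi, sector)

    nbins = len(q_edges) - 1
    idx = np.digitize(qmap.q_r[sel], q_edges) - 1
    inside = (idx >= 0) & (idx < nbins)
    idx = idx[inside]
    vals = image.counts[sel][inside]

    n_pixels = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(n_pixels > 0, sums / np.maximum(n_pixels, 1), np.nan)

    return RadialProfile(
        q_centers=0.5 * (q_edges[:-1] + q_edges[1:]),
        q_edges=q_edges,
        intensity=intensity,
        n_pixels=n_pixels,
        sector=None if sector is None else [tuple(w) for w in sector],
    )


def radial_integrate(
    image: DetectorImage,
    qmap: QChiMap,
    chi_edges: np.ndarray,
    q_range: tuple[float, float],
    n_radial_subbins: int = 64,
) -> AzimuthalProfile:
    """Integrate I(q_r, chi) over q_r in ``q_range`` for each chi bin.

    Within each chi bin the annulus is split into ``n_radial_subbins`` radial
    sub-bins; the mean intensity of each sub-bin is integrated over q by the
    trapezoidal rule (with constant extension to the band edges), which makes
    H independent of how many pixels happen to fall in each annulus.  A chi
    bin whose annulus contains no usable pixels is returned as NaN.
    """
    qmin, qmax = map(float, q_range)
    if not qmin < qmax:
        raise ReductionError(f"require qmin < qmax, got ({qmin}, {qmax})")
    chi_edges = np.asarray(chi_edges, dtype=float)
    nchi = len(chi_edges) - 1
    if nchi < 1 or np.any(np.diff(chi_edges) <= 0):
        raise ReductionError("chi_edges must be strictly increasing")

    usable = image.mask & qmap.valid
    sel = usable & (qmap.q_r >= qmin) & (qmap.q_r <= qmax)
    if not sel.any():
        raise ReductionError("no usable pixels inside the q band")

    bin_centers = 0.5 * (chi_edges[:-1] + chi_edges[1:])
    chi_idx = np.digitize(qmap.chi[sel], chi_edges) - 1
    ok = (chi_idx >= 0) & (chi_idx < nchi)
    sub_edges = np.linspace(qmin, qmax, n_radial_subbins + 1)
    sub_idx = np.clip(np.digitize(qmap.q_r[sel], sub_edges) - 1, 0, n_radial_subbins - 1)

    flat = chi_idx[ok] * n_radial_subbins + sub_idx[ok]
    vals = image.counts[sel][ok]
    # pixel azimuth relative to the nominal bin centre (wrap-safe)
    chi_off = qmap.chi[sel][ok] - bin_centers[chi_idx[ok]]
    chi_off = (chi_off + math.pi) % TWO_PI - math.pi
    size = nchi * n_radial_subbins
    cnt = np.bincount(flat, minlength=size).reshape(nchi, n_radial_subbins)
    tot = np.bincount(flat, weights=vals, minlength=size).reshape(nchi, n_radial_subbins)
    ctot = np.bincount(flat, weights=chi_off, minlength=size).reshape(nchi, n_radial_subbins)

    sub_centers = 0.5 * (sub_edges[:-1] + sub_edges[1:])
    H = np.full(nchi, np.nan)
    chi_eff = bin_centers.copy()
    for i in range(nchi):
        nz = cnt[i] > 0
        if nz.sum() < 2:
            continue
        means = tot[i, nz] / cnt[i, nz]
        centers = sub_centers[nz]
        # extend the first/last sub-bin mean to the band edges so a constant
        # intensity integrates exactly to c * (qmax - qmin)
        nodes = np.concatenate([[qmin], centers, [qmax]])
        values = np.concatenate([[means[0]], means, [means[-1]]])
        H[i] = np.trapezoid(values, nodes)
        # effective azimuth node: mean pixel azimuth weighted by each
        # sub-bin's contribution (|mean| x dq) to the integral
        w = np.abs(means) * np.gradient(nodes)[1:-1]
        if w.sum() > 0:
            chi_eff[i] = bin_centers[i] + float(
                np.sum(w * (ctot[i, nz] / cnt[i, nz])) / np.sum(w)
            )

    return AzimuthalProfile(
        chi_centers=chi_eff,
        H=H,
        q_range=(qmin, qmax),
        n_pixels=cnt.sum(axis=1),
    )


def fold_half_quadrant(profile: AzimuthalProfile, n_bins: int | None = None) -> AzimuthalProfile:
    """Fold a full-circle H(chi) onto [0, pi/2] about the streak axis.

    A streak from centrosymmetric scattering gives H two equivalent peaks at
    chi0 and chi0 + pi.  The profile is aligned so the circular argmax sits at
    zero, then folded by chi -> min(chi mod pi, pi - chi mod pi) and averaged
    over the contributing bins.
    """
    ne = profile.nonempty
    if not ne.any():
        raise ReductionError("cannot fold an all-empty profile")
    chi = np.asarray(profile.chi_centers, dtype=float)
    chi0 = chi[ne][np.argmax(profile.H[ne])]

    delta = (chi - chi0) % math.pi
    folded = np.minimum(delta, math.pi - delta)

    if n_bins is None:
        n_bins = max(1, round(len(chi) / 4))
    edges = np.linspace(0.0, math.pi / 2.0, n_bins + 1)
    idx = np.clip(np.digitize(folded, edges) - 1, 0, n_bins - 1)

    chi_out = 0.5 * (edges[:-1] + edges[1:])
    H_out = np.full(n_bins, np.nan)
    n_out = np.zeros(n_bins)
    for b in range(n_bins):
        m = (idx == b) & ne
        if m.any():
            H_out[b] = float(np.mean(profile.H[m]))
            chi_out[b] = float(np.mean(folded[m]))  # effective node of the folded bin
            if profile.n_pixels is not None:
                n_out[b] = float(np.sum(profile.n_pixels[m]))
    order = np.argsort(chi_out)
    return AzimuthalProfile(
        chi_centers=chi_out[order],
        H=H_out[order],
        q_range=profile.q_range,
        n_pixels=n_out[order],
    )


def anisotropy_score(profile: AzimuthalProfile) -> float:
    """Peak-to-valley contrast of H(chi): (max - min) / mean over nonempty bins.

    Zero for a perfectly isotropic (constant) profile; large for streaks.
    """
    H = profile.H[profile.nonempty]
    if len(H) < 8:
        raise ReductionError(f"need >= 8 nonempty chi bins, got {len(H)}")
    mean = float(np.mean(H))
    if mean == 0.0:
        raise ReductionError("anisotropy score undefined for zero-mean profile")
    return float((np.max(H) - np.min(H)) / mean)


def subtract_isotropic_floor(profile: AzimuthalProfile, percentile: float = 5.0) -> AzimuthalProfile:
    """Subtract the isotropic background floor from H(chi).

    The floor is estimated as the given percentile of H over nonempty bins
    (default 5th).  Values driven negative are kept (not clipped): the
    inversion's non-negative model pulls them toward zero, whereas clipping
    would rectify tail noise into a positive bias.  The oriented component of
    the scattering is what the orientation transform models, so this is
    applied before inversion.
    """
    ne = profile.nonempty
    if not ne.any():
        raise ReductionError("cannot subtract floor of an all-empty profile")
    floor = float(np.percentile(profile.H[ne], percentile))
    H = np.where(ne, profile.H - floor, np.nan)
    return AzimuthalProfile(
        chi_centers=profile.chi_centers.copy(),
        H=H,
        q_range=profile.q_range,
        n_pixels=None if profile.n_pixels is None else profile.n_pixels.copy(),
    )
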