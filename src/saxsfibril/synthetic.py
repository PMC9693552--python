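"""Seeded synthetic 2D scattering patterns with known ground truth.

Two regimes of bacterial-cellulose scattering are emulated:

* ``streaked`` — near-parallel microfibrils produce symmetric radial streaks.
  The noiseless intensity is ``A * q^-alpha * H_true(chi)`` where ``H_true``
  is the azimuthal profile obtained by pushing a truncated-Gaussian fibril
  angle density of chosen RMS through the orientation transform — the same
  integral equation the analysis inverts, so recovery tests are true round
  trips (an independent quadrature oracle in the test suite guards against a
  shared bug).
* ``isotropic`` — disordered material gives a circularly symmetric pattern:
  a power-law background plus a broad Gaussian ridge at ``peak_q``
  (real-space period ``2*pi / peak_q``).

Photon noise is pure Poisson (hybrid photon-counting detectors add no read
noise); a beamstop disk and two horizontal detector-gap bands are masked.
The expected total count over usable pixels equals ``photon_budget``, with an
``isotropic_background`` fraction of it spread flat over the detector.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Literal

import numpy as np

from .geometry import ExperimentGeometry, build_q_chi_map
from .orientation import forward_transform, truncated_gaussian
from .reduction import DetectorImage

__all__ = [
    "SyntheticSampleSpec",
    "default_geometry",
    "generate_pattern",
    "expected_intensity",
    "preset_old_culture",
    "preset_young_culture",
]


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Ground-truth parameters for one simulated pattern."""

    kind: Literal["streaked", "isotropic"]
    decay_exponent: float
    photon_budget: float
    seed: int = 0
    fibril_rms_deg: float | None = None  # streaked only
    peak_q: float | None = None  # nm^-1, isotropic only
    peak_sigma_q: float | None = None  # nm^-1
    peak_amplitude_ratio: float | None = None  # ridge height / baseline at peak_q
    isotropic_background: float = 0.05  # fraction of budget in a flat floor
    q_valid_range: tuple[float, float] = (0.15, 5.0)

    def __post_init__(self) -> None:
        if self.kind not in ("streaked", "isotropic"):
            raise SyntheticSpecError(f"unknown kind {self.kind!r}")
        if self.photon_budget <= 0:
            raise SyntheticSpecError("photon_budget must be positive")
        if self.kind == "streaked" and not (self.fibril_rms_deg and self.fibril_rms_deg > 0):
            raise SyntheticSpecError("streaked patterns require fibril_rms_deg > 0")
        peak_fields = (self.peak_q, self.peak_sigma_q, self.peak_amplitude_ratio)
        if any(v is not None for v in peak_fields) and not all(v is not None for v in peak_fields):
            raise SyntheticSpecError("peak_q, peak_sigma_q, peak_amplitude_ratio must be set together")
        if not 0.0 <= self.isotropic_background < 1.0:
            raise SyntheticSpecError("isotropic_background must be in [0, 1)")
        qlo, qhi = self.q_valid_range
        if not 0 < qlo < qhi:
            raise SyntheticSpecError("q_valid_range must satisfy 0 < qmin < qmax")


def default_geometry(shape: tuple[int, int] = (512, 512), pixel_size_mm: float = 0.4) -> ExperimentGeometry:
    """Desk-scale stand-in for the beamline setup (synthetic).

    Wavelength 0.2 nm and sample-detector distance 982.8 mm as at the
    beamline; a 512x512 grid of 0.4 mm pixels emulates the central ~205 mm of
    a Pilatus-class detector at reduced resolution, reaching q ~ 3.3 nm^-1 at
    the edge — enough to cover both the power-law window and the broad-peak
    region.  Pass a larger ``shape`` for full-size frames.
    """
    nr, nc = shape
    return ExperimentGeometry(
        wavelength_nm=0.2,
        distance_mm=982.8,
        beam_center=((nr - 1) / 2.0, (nc - 1) / 2.0),
        pixel_size_mm=pixel_size_mm,
        detector_shape=(int(nr), int(nc)),
    )


def preset_old_culture(photon_budget: float = 1e7, seed: int = 0) -> SyntheticSampleSpec:
    """Mature-culture regime: streaks from near-parallel fibrils.

    RMS fibril angle 3.3 degrees and radial decay q^-2.03, the values
    characterizing the densely packed cellulose chamber envelope.
    """
    return SyntheticSampleSpec(
        kind="streaked",
        fibril_rms_deg=3.3,
        decay_exponent=2.03,
        photon_budget=photon_budget,
        seed=seed,
    )


def preset_young_culture(
    photon_budget: float = 1e7, seed: int = 0, period_nm: float | None = None
) -> SyntheticSampleSpec:
    """Young-culture regime: circularly symmetric pattern with a broad peak.

    By default the peak sits at q = 0.85 nm^-1; pass ``period_nm`` to place
    it at ``2*pi / period_nm`` instead (e.g. 7.5 nm -> q ~ 0.8378 nm^-1).
    """
    peak_q = 0.85 if period_nm is None else 2.0 * math.pi / period_nm
    return SyntheticSampleSpec(
        kind="isotropic",
        decay_exponent=1.0,
        photon_budget=photon_budget,
        seed=seed,
        peak_q=peak_q,
        peak_sigma_q=0.3,
        peak_amplitude_ratio=1.5,
    )


def _fold_chi(chi: np.ndarray) -> np.ndarray:
    """Map azimuth to the fibril-angle coordinate in [0, pi/2] about chi = 0."""
    delta = np.mod(chi, math.pi)
    return np.minimum(delta, math.pi - delta)


def _detector_mask(shape: tuple[int, int], beam_center: tuple[float, float],
                   beamstop_radius_px: float = 6.0) -> np.ndarray:
    """Usable-pixel mask: beamstop disk plus two horizontal module-gap bands."""
    nr, nc = shape
    mask = np.ones((nr, nc), dtype=bool)
    band = max(2, nr // 64)
    # two bands placed centro-symmetrically about the detector centre so the
    # usable area (and hence the noiseless intensity) keeps the point symmetry
    start = nr // 3
    mask[start : start + band, :] = False
    mask[nr - start - band : nr - start, :] = False
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    rpx = np.hypot(rows - beam_center[0], cols - beam_center[1])
    mask[rpx <= beamstop_radius_px] = False
    return mask


def ground_truth_orientation(spec: SyntheticSampleSpec, n: int = 512):
    """The fibril-angle density the streaked pattern is generated from."""
    if spec.kind != "streaked":
        return None
    return truncated_gaussian(spec.fibril_rms_deg, n=n)


def ground_truth_azimuthal(spec: SyntheticSampleSpec, n: int = 512):
    """Noise-free H(chi) of the streaked ground truth on a fine chi grid."""
    f = ground_truth_orientation(spec, n=n)
    if f is None:
        return None
    chi = np.linspace(0.0, math.pi / 2.0, n, endpoint=False)
    return forward_transform(f, chi)


def expected_intensity(
    spec: SyntheticSampleSpec, geometry: ExperimentGeometry | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected counts per pixel and the usable-pixel mask.

    The structured component is normalized so that, together with the flat
    background fraction, the expected total over usable pixels equals
    ``photon_budget``.
    """
    if geometry is None:
        geometry = default_geometry()
    qmap = build_q_chi_map(geometry)
    mask = _detector_mask(geometry.detector_shape, geometry.beam_center) & qmap.valid

    qlo, qhi = spec.q_valid_range
    q = qmap.q_r
    in_range = (q >= qlo) & (q <= qhi)
    q_safe = np.where(in_range, q, 1.0)

    if spec.kind == "streaked":
        H_true = ground_truth_azimuthal(spec)
        shape_fac = np.interp(_fold_chi(qmap.chi), H_true.chi_centers, H_true.H)
        shape = np.where(in_range, q_safe ** (-spec.decay_exponent) * shape_fac, 0.0)
    else:
        q_det_max = float(q[mask].max()) if mask.any() else 0.0
        if spec.peak_q is not None and not (qlo <= spec.peak_q <= min(qhi, q_det_max)):
            raise SyntheticSpecError(
                f"peak_q={spec.peak_q} outside the usable detector q range "
                f"[{qlo}, {min(qhi, q_det_max):.3g}]"
            )
        shape = q_safe ** (-spec.decay_exponent)
        if spec.peak_q is not None:
            ridge = (
                spec.peak_amplitude_ratio
                * spec.peak_q ** (-spec.decay_exponent)
                * np.exp(-0.5 * ((q - spec.peak_q) / spec.peak_sigma_q) ** 2)
            )
            shape = shape + ridge
        shape = np.where(in_range, shape, 0.0)

    total = float(shape[mask].sum())
    if total <= 0:
        raise SyntheticSpecError("structured intensity vanishes on the usable detector area")
    w = spec.isotropic_background
    lam = np.zeros_like(shape)
    lam[mask] = spec.photon_budget * (
        (1.0 - w) * shape[mask] / total + w / mask.sum()
    )
    return lam, mask


def generate_pattern(
    spec: SyntheticSampleSpec, geometry: ExperimentGeometry | None = None
) -> DetectorImage:
    """Draw a Poisson realization of the synthetic pattern.

    The same spec and seed always produce a bit-identical image; all
    randomness flows from a single ``numpy`` generator seeded with
    ``spec.seed``.
    """
    if geometry is None:
        geometry = default_geometry()
    lam, mask = expected_intensity(spec, geometry)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(lam).astype(float)
    counts[~mask] = 0.0
    meta = {"synthetic": True, "spec": asdict(spec), "geometry": geometry.to_dict()}
    return DetectorImage(counts=counts, mask=mask, metadata=meta)


def with_seed(spec: SyntheticSampleSpec, seed: int) -> SyntheticSampleSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=int(seed))
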