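"""End-to-end analysis of one detector image.

The pipeline mirrors how a fibre-diffraction analyst works through a SAXS
frame: build the (q_r, chi) map, compute the azimuthal profile H(chi) over a
q band, and branch on its anisotropy.

* Anisotropic (streaked) frames: average I(q_r) over the streak wedges and
  fit the power-law decay; fold H onto [0, pi/2] about the streak axis,
  subtract the isotropic floor, invert the orientation transform and report
  the RMS fibril angle.
* Isotropic frames: average I(q_r) over the full circle and search for a
  broad correlation peak, reporting the real-space period 2*pi/q_peak.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .geometry import ExperimentGeometry, build_q_chi_map
from .io import (
    geometry_hash,
    load_image,
    write_azimuthal_csv,
    write_orientation_csv,
    write_radial_csv,
)
from .orientation import OrientationDistribution, invert_orientation, rms_angle
from .profile_models import PeakFit, PowerLawFit, detect_broad_peak, fit_power_law
from .reduction import (
    AzimuthalProfile,
    DetectorImage,
    RadialProfile,
    anisotropy_score,
    azimuthal_average,
    fold_half_quadrant,
    radial_integrate,
    subtract_isotropic_floor,
)
from .synthetic import default_geometry

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "write_report", "validate_report"]

log = logging.getLogger("saxsfibril")

TWO_PI = 2.0 * math.pi


@dataclass
class AnalysisConfig:
    """All tunables of the analysis, with documented defaults.

    Angles are degrees here (radians are internal only); q values are nm^-1.
    """

    geometry: ExperimentGeometry = field(default_factory=default_geometry)
    #: chi binning over the full circle; 720 bins = 0.5 deg/bin, fine enough
    #: to resolve orientation spreads of a few degrees.
    n_chi_bins: int = 720
    #: q band of the radial integral defining H(chi).
    h_q_range: tuple[float, float] = (0.3, 2.0)
    #: range and bin count of the radial profile I(q_r).
    q_profile_range: tuple[float, float] = (0.15, 3.2)
    n_q_bins: int = 160
    #: window of the power-law fit (the low-q region where intraparticle
    #: interference dominates).
    power_law_q_window: tuple[float, float] = (0.4, 1.8)
    #: half-width of each streak wedge for sector averaging.
    sector_half_width_deg: float = 15.0
    #: half-width of the reference wedges (perpendicular to the streak) used
    #: to estimate the isotropic floor of the sector-averaged I(q).
    floor_sector_half_width_deg: float = 30.0
    #: q bins whose pixel count inside the sector falls below this fraction
    #: of the unmasked reference are dropped from the power-law fit: a
    #: detector gap crossing the streak removes an unrepresentative part of
    #: the azimuthal range and biases the annulus mean.
    min_sector_coverage: float = 0.98
    #: (max-min)/mean of H above which a frame is called anisotropic.
    anisotropy_threshold: float = 0.5
    #: Tikhonov weight of the orientation inversion, relative to ||M||.
    regularization: float = 1e-3
    #: percentile of H used as the isotropic floor before inversion.
    baseline_percentile: float = 5.0
    n_radial_subbins: int = 64

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "AnalysisConfig":
        cfg = dict(cfg)
        geom = cfg.pop("geometry", None)
        kwargs: dict[str, Any] = {}
        if geom is not None:
            kwargs["geometry"] = ExperimentGeometry.from_dict(geom)
        for key in (
            "n_chi_bins", "h_q_range", "q_profile_range", "n_q_bins",
            "power_law_q_window", "sector_half_width_deg",
            "floor_sector_half_width_deg", "min_sector_coverage",
            "anisotropy_threshold", "regularization", "baseline_percentile",
            "n_radial_subbins",
        ):
            if key in cfg:
                v = cfg[key]
                kwargs[key] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(cfg or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "geometry": self.geometry.to_dict(),
            "n_chi_bins": self.n_chi_bins,
            "h_q_range": list(self.h_q_range),
            "q_profile_range": list(self.q_profile_range),
            "n_q_bins": self.n_q_bins,
            "power_law_q_window": list(self.power_law_q_window),
            "sector_half_width_deg": self.sector_half_width_deg,
            "floor_sector_half_width_deg": self.floor_sector_half_width_deg,
            "min_sector_coverage": self.min_sector_coverage,
            "anisotropy_threshold": self.anisotropy_threshold,
            "regularization": self.regularization,
            "baseline_percentile": self.baseline_percentile,
            "n_radial_subbins": self.n_radial_subbins,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Everything the analysis concluded about one frame."""

    classification: str  # "anisotropic_streaked" | "isotropic"
    anisotropy_score: float
    power_law: PowerLawFit | None = None
    peak: PeakFit | None = None
    orientation: OrientationDistribution | None = None
    rms_deg: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    # full profiles kept for CSV export; not serialized into the JSON report
    radial_profile: RadialProfile | None = field(default=None, repr=False)
    azimuthal_profile: AzimuthalProfile | None = field(default=None, repr=False)

    def to_dict(self, include_timestamp: bool = True) -> dict[str, Any]:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        return {
            "classification": self.classification,
            "anisotropy_score": self.anisotropy_score,
            "power_law": self.power_law.to_dict() if self.power_law else None,
            "peak": self.peak.to_dict() if self.peak else None,
            "orientation": None
            if self.orientation is None
            else {"rms_deg": self.rms_deg, "n_mu_bins": len(self.orientation.mu_centers)},
            "errors": list(self.errors),
            "provenance": prov,
        }


def validate_report(report: dict[str, Any]) -> None:
    """Check a report dict against the published schema; raise on violation."""
    required = {"classification", "anisotropy_score", "power_law", "peak", "orientation", "errors", "provenance"}
    missing = required - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["classification"] not in ("anisotropic_streaked", "isotropic"):
        raise ValueError(f"bad classification {report['classification']!r}")
    if not isinstance(report["anisotropy_score"], (int, float)):
        raise ValueError("anisotropy_score must be a number")
    if report["classification"] == "anisotropic_streaked":
        if report["power_law"] is None or report["orientation"] is None:
            if not report["errors"]:
                raise ValueError("anisotropic report lacks power_law/orientation without errors")
    else:
        if report["peak"] is None and not report["errors"]:
            raise ValueError("isotropic report lacks peak analysis without errors")


def _streak_sector(chi0: float, half_width_rad: float) -> list[tuple[float, float]]:
    """Two centrosymmetric wedges of the given half-width around the streak."""
    return [
        ((chi0 - half_width_rad) % TWO_PI, (chi0 + half_width_rad) % TWO_PI),
        ((chi0 + math.pi - half_width_rad) % TWO_PI, (chi0 + math.pi + half_width_rad) % TWO_PI),
    ]


def run_analysis(
    image: DetectorImage | str | Path,
    config: AnalysisConfig | None = None,
    mask_path: str | Path | None = None,
) -> AnalysisReport:
    """Classify a frame and run the matching analysis branch.

    ``image`` may be a :class:`DetectorImage` or a path to a TIFF/NPY file
    (with an optional separate mask file).  Fit failures inside a branch are
    recorded in ``report.errors``, never silently dropped.
    """
    if config is None:
        config = AnalysisConfig()
    if not isinstance(image, DetectorImage):
        image = load_image(image, mask_path)
    if image.counts.shape != config.geometry.detector_shape:
        raise ValueError(
            f"image shape {image.counts.shape} does not match configured detector "
            f"shape {config.geometry.detector_shape}"
        )

    qmap = build_q_chi_map(config.geometry)
    chi_edges = np.linspace(0.0, TWO_PI, config.n_chi_bins + 1)
    H_full = radial_integrate(
        image, qmap, chi_edges, config.h_q_range, n_radial_subbins=config.n_radial_subbins
    )
    score = anisotropy_score(H_full)
    anis = score > config.anisotropy_threshold
    classification = "anisotropic_streaked" if anis else "isotropic"
    log.info("anisotropy score %.3f -> %s", score, classification)

    q_edges = np.linspace(*config.q_profile_range, config.n_q_bins + 1)
    errors: list[str] = []
    power_law = peak = orientation = None
    rms = None

    if anis:
        ne = H_full.nonempty
        chi0 = float(H_full.chi_centers[ne][np.argmax(H_full.H[ne])])
        sector = _streak_sector(chi0, math.radians(config.sector_half_width_deg))
        radial = azimuthal_average(image, qmap, q_edges, sector=sector)
        # the power-law fit sees the oriented component only: subtract the
        # isotropic floor measured perpendicular to the streak, and drop q
        # bins whose azimuthal coverage inside the sector is incomplete
        # (a gap crossing the streak biases the annulus mean)
        perp = _streak_sector(
            chi0 + math.pi / 2.0, math.radians(config.floor_sector_half_width_deg)
        )
        floor = azimuthal_average(image, qmap, q_edges, sector=perp)
        reference = azimuthal_average(
            DetectorImage(counts=np.ones_like(image.counts)), qmap, q_edges, sector=sector
        )
        coverage = radial.n_pixels / np.maximum(reference.n_pixels, 1)
        good = radial.nonempty & (coverage >= config.min_sector_coverage)
        fit_profile = RadialProfile(
            q_centers=radial.q_centers,
            q_edges=radial.q_edges,
            intensity=np.where(good, radial.intensity - floor.intensity, np.nan),
            n_pixels=np.where(good, radial.n_pixels, 0),
            sector=radial.sector,
        )
        try:
            power_law = fit_power_law(fit_profile, config.power_law_q_window)
            log.info(
                "power-law exponent %.4f +/- %.4f (r^2 = %.4f)",
                power_law.exponent, power_law.stderr_exponent, power_law.r_squared,
            )
        except ValueError as exc:
            errors.append(f"power-law fit failed: {exc}")
        try:
            folded = fold_half_quadrant(H_full)
            cleaned = subtract_isotropic_floor(folded, config.baseline_percentile)
            orientation = invert_orientation(cleaned, regularization=config.regularization)
            rms = rms_angle(orientation)
            log.info("RMS fibril angle %.3f deg", rms)
        except ValueError as exc:
            errors.append(f"orientation inversion failed: {exc}")
    else:
        radial = azimuthal_average(image, qmap, q_edges, sector=None)
        try:
            peak = detect_broad_peak(radial)
            if peak.found:
                log.info(
                    "broad peak at q = %.4f nm^-1 (period %.2f nm)", peak.q_peak, peak.period_nm
                )
            else:
                log.info("no significant broad peak: %s", peak.message)
        except ValueError as exc:
            errors.append(f"peak detection failed: {exc}")

    report = AnalysisReport(
        classification=classification,
        anisotropy_score=score,
        power_law=power_law,
        peak=peak,
        orientation=orientation,
        rms_deg=rms,
        errors=errors,
        provenance={
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "geometry_hash": geometry_hash(config.geometry.to_dict()),
            "config": config.to_dict(),
            "image_metadata_seed": image.metadata.get("spec", {}).get("seed")
            if isinstance(image.metadata.get("spec"), dict) else None,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        radial_profile=radial,
        azimuthal_profile=H_full,
    )
    return report


def write_report(report: AnalysisReport, path: str | Path, out_dir: str | Path | None = None) -> None:
    """Write the JSON report (schema-validated) and, optionally, CSV profiles."""
    d = report.to_dict()
    validate_report(d)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hdr = {"geometry_hash": d["provenance"]["geometry_hash"]}
        if report.radial_profile is not None:
            write_radial_csv(report.radial_profile, out_dir / "radial_profile.csv", hdr)
        if report.azimuthal_profile is not None:
            write_azimuthal_csv(report.azimuthal_profile, out_dir / "azimuthal_profile.csv", hdr)
        if report.orientation is not None:
            write_orientation_csv(
                report.orientation.mu_centers, report.orientation.density,
                out_dir / "orientation.csv",
            )
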