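"""Reading and writing of images, profiles and reports.

Images travel as single-plane TIFF (via tifffile) or NPY; masks as 0/1 arrays
in either format.  Profiles are CSV with ``#`` header comments recording the
q range, sector and geometry hash, so a reduction can be audited from its
outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .reduction import AzimuthalProfile, DetectorImage, RadialProfile


class IOError_(ValueError):
    pass


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    if path.suffix.lower() == ".npy":
        return np.load(path)
    raise IOError_(f"{path}: unsupported format {path.suffix!r} (expected .tif/.tiff or .npy)")


def _save_array(path: Path, arr: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".npy":
        np.save(path, arr)
    else:
        raise IOError_(f"{path}: unsupported format {path.suffix!r} (expected .tif/.tiff or .npy)")


def load_image(path: str | Path, mask_path: str | Path | None = None) -> DetectorImage:
    """Load a detector image (TIFF or NPY), optionally with a 0/1 mask file."""
    path = Path(path)
    counts = _load_array(path)
    if counts.ndim != 2:
        raise IOError_(f"{path}: expected a single-plane 2D image, got shape {counts.shape}")
    mask = None
    if mask_path is not None:
        mask = _load_array(Path(mask_path)).astype(bool)
    return DetectorImage(counts=counts, mask=mask, metadata={"source": str(path)})


def save_image(image: DetectorImage, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write counts (and optionally the mask as uint8 0/1) to TIFF or NPY."""
    counts = image.counts
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.uint32)
    _save_array(Path(path), counts)
    if mask_path is not None:
        _save_array(Path(mask_path), image.mask.astype(np.uint8))


def geometry_hash(geometry_dict: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(geometry_dict, sort_keys=True).encode()).hexdigest()[:12]


def write_radial_csv(profile: RadialProfile, path: str | Path, header: dict[str, Any] | None = None) -> None:
    lines = ["# radial profile"]
    if profile.sector is not None:
        lines.append(f"# sector_rad = {json.dumps([list(w) for w in profile.sector])}")
    else:
        lines.append("# sector_rad = full_circle")
    for k, v in (header or {}).items():
        lines.append(f"# {k} = {v}")
    lines.append("q_nm_inv,intensity,n_pixels")
    for q, I, n in zip(profile.q_centers, profile.intensity, profile.n_pixels):
        lines.append(f"{q:.9g},{'' if not np.isfinite(I) else format(I, '.9g')},{int(n)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_azimuthal_csv(profile: AzimuthalProfile, path: str | Path, header: dict[str, Any] | None = None) -> None:
    lines = ["# azimuthal profile H(chi)"]
    if profile.q_range is not None:
        lines.append(f"# q_range_nm_inv = [{profile.q_range[0]:.9g}, {profile.q_range[1]:.9g}]")
    for k, v in (header or {}).items():
        lines.append(f"# {k} = {v}")
    lines.append("chi_deg,H,n_pixels")
    npix = profile.n_pixels if profile.n_pixels is not None else np.zeros(len(profile.H))
    for chi, H, n in zip(profile.chi_centers, profile.H, npix):
        lines.append(
            f"{np.degrees(chi):.9g},{'' if not np.isfinite(H) else format(H, '.9g')},{int(n)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_azimuthal_csv(path: str | Path) -> AzimuthalProfile:
    """Read back an azimuthal-profile CSV written by :func:`write_azimuthal_csv`."""
    q_range = None
    chi, H, npix = [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "q_range_nm_inv" in line:
                q_range = tuple(json.loads(line.split("=", 1)[1].strip()))
            continue
        if line.startswith("chi_deg"):
            continue
        parts = line.split(",")
        chi.append(np.radians(float(parts[0])))
        H.append(float(parts[1]) if parts[1] != "" else np.nan)
        npix.append(float(parts[2]) if len(parts) > 2 and parts[2] != "" else 0.0)
    return AzimuthalProfile(
        chi_centers=np.asarray(chi), H=np.asarray(H), q_range=q_range, n_pixels=np.asarray(npix)
    )


def write_orientation_csv(mu_centers: np.ndarray, density: np.ndarray, path: str | Path) -> None:
    lines = ["# fibril angle distribution f(mu)", "mu_deg,density"]
    for mu, f in zip(mu_centers, density):
        lines.append(f"{np.degrees(mu):.9g},{f:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")
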