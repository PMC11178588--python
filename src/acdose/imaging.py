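"""Calibrated activity quantification and SUV extraction from SPECT volumes.

Reconstructed multi-photopeak volumes arrive in counts per second per voxel
(cps/voxel).  A phantom-derived calibration factor converts them to Bq/ml,
after which VOI statistics (mean/max concentration, volume, total activity)
and mean standardized uptake values are read out.  Lesions are segmented on
the Gaussian-post-filtered 24 h image with an 80 % of maximum isocontour;
kidney masks are CT-based and consumed as supplied files.  No recovery or
partial-volume correction is applied anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError, SegmentationError

log = logging.getLogger(__name__)

#: FWHM of a unit-variance Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class EnergyWindow:
    """Photopeak acquisition window: center (keV) and percent width."""

    center_kev: float
    width_percent: float

    def __str__(self):
        return f"{self.center_kev:g} keV / {self.width_percent:g}%"


# The three windows used for Ac-225 chain imaging.
WINDOW_BI213 = EnergyWindow(440.0, 20.0)
WINDOW_FR221 = EnergyWindow(218.0, 20.0)
WINDOW_XRAY = EnergyWindow(78.0, 50.0)


@dataclass(frozen=True)
class QuantImage:
    """A 3D quantitative volume with acquisition metadata.

    ``units`` tracks the physical meaning of voxel values and is updated by
    every operation; mixing units raises a :class:`ConfigurationError`.
    """

    voxels: np.ndarray  # 3D
    voxel_size: tuple[float, float, float]  # mm
    units: str  # "cps/voxel", "Bq/ml" or "SUV"
    time_post_injection: float  # hours
    energy_window: EnergyWindow
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise InvalidInputError("QuantImage requires a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("voxel values must be finite")
        if any(s <= 0 for s in self.voxel_size):
            raise InvalidInputError("voxel size components must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm³ / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        return img

    def save(self, path):
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path, units, time_post_injection, energy_window):
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, zooms, units, time_post_injection, energy_window, img.affine)


@dataclass(frozen=True)
class VOIMask:
    """Binary mask congruent with its image."""

    voxels: np.ndarray  # bool
    label: str
    origin: str = "ct_based"  # or "isocontour_80"

    def __post_init__(self):
        if self.voxels.dtype != bool:
            object.__setattr__(self, "voxels", self.voxels.astype(bool))
        if not self.voxels.any():
            raise SegmentationError(f"mask {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def shifted(self, offset: tuple[int, int, int]) -> "VOIMask":
        """Integer-voxel translation (manual re-alignment of a 24 h mask at 48 h)."""
        rolled = np.roll(self.voxels, offset, axis=(0, 1, 2))
        return replace(self, voxels=rolled)

    def save(self, path, affine=None):
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), np.eye(4) if affine is None else affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, label, origin="ct_based"):
        data = np.asarray(nib.load(str(path)).get_fdata()) > 0.5
        return cls(data, label, origin)


@dataclass(frozen=True)
class CalibrationFactor:
    """(cps/voxel) per (Bq/ml) for one energy window."""

    value: float
    energy_window: EnergyWindow
    provenance: str = ""

    def __post_init__(self):
        if not self.value > 0:
            raise InvalidInputError("calibration factor must be positive")


@dataclass(frozen=True)
class VOIQuant:
    """Per-VOI quantitative readout."""

    mean_concentration: float  # Bq/ml
    max_concentration: float  # Bq/ml
    volume: float  # ml
    total_activity: float  # Bq
    suv_mean: float


def _check_congruent(image: QuantImage, mask: VOIMask):
    if image.voxels.shape != mask.voxels.shape:
        raise ConfigurationError(
            f"mask shape {mask.voxels.shape} does not match image {image.voxels.shape}"
        )


def compute_calibration_factor(
    phantom_image: QuantImage, known_concentration: float, voi: VOIMask
) -> CalibrationFactor:
    """Calibration factor from a uniformly filled phantom acquisition.

    Mean cps/voxel inside the VOI divided by the known activity concentration.
    """
    if phantom_image.units != "cps/voxel":
        raise ConfigurationError(f"phantom image must be cps/voxel, got {phantom_image.units!r}")
    if not known_concentration > 0:
        raise InvalidInputError("known concentration must be positive")
    _check_congruent(phantom_image, voi)
    mean_cps = float(phantom_image.voxels[voi.voxels].mean())
    return CalibrationFactor(
        value=mean_cps / known_concentration,
        energy_window=phantom_image.energy_window,
        provenance=f"phantom VOI '{voi.label}', {voi.n_voxels} voxels",
    )


def apply_calibration(image: QuantImage, factor: CalibrationFactor) -> QuantImage:
    """Convert a cps/voxel image to Bq/ml by voxelwise division."""
    if image.units != "cps/voxel":
        raise ConfigurationError(f"expected cps/voxel image, got {image.units!r}")
    if image.energy_window != factor.energy_window:
        raise ConfigurationError(
            f"energy window mismatch: image {image.energy_window}, factor {factor.energy_window}"
        )
    return replace(image, voxels=image.voxels / factor.value, units="Bq/ml")


def gaussian_postfilter(image: QuantImage, fwhm_mm: float) -> QuantImage:
    """Isotropic Gaussian noise-suppression filter.

    ``fwhm_mm`` is converted to a per-axis sigma in voxels via the voxel
    size.  Zero-padding boundary handling conserves the total image sum for
    interior-supported images.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InvalidInputError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return image
    sigmas = [fwhm_mm / FWHM_PER_SIGMA / s for s in image.voxel_size]
    filtered = ndimage.gaussian_filter(image.voxels, sigma=sigmas, mode="constant", cval=0.0)
    return replace(image, voxels=filtered)


def isocontour_mask(
    image: QuantImage,
    search_region: VOIMask,
    fraction: float = 0.8,
    label: str = "lesion",
) -> VOIMask:
    """Threshold segmentation at ``fraction`` of the regional maximum.

    Voxels inside ``search_region`` with value ≥ fraction × max are kept,
    restricted to the connected component containing the maximum (26-
    connectivity).  With several equal maxima in separate blobs the first in
    lexicographic scan order wins and a warning is emitted.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidInputError("fraction must lie in (0, 1)")
    _check_congruent(image, search_region)
    region_values = np.where(search_region.voxels, image.voxels, -np.inf)
    vmax = region_values.max()
    if not np.isfinite(vmax):
        raise SegmentationError("search region is empty")
    above = region_values >= fraction * vmax
    if not above.any():
        raise SegmentationError("isocontour produced an empty mask")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, _ = ndimage.label(above, structure=structure)
    max_positions = np.argwhere(region_values == vmax)
    if len(max_positions) > 1:
        blobs = {labels[tuple(p)] for p in max_positions}
        if len(blobs) > 1:
            warnings.warn(
                "multiple equal maxima in separate components; "
                "keeping the first in scan order",
                stacklevel=2,
            )
            log.warning("isocontour tie: %d equal maxima across %d components",
                        len(max_positions), len(blobs))
    keep = labels == labels[tuple(max_positions[0])]
    return VOIMask(keep, label=label, origin=f"isocontour_{int(round(fraction * 100))}")


def voi_quant(
    image: QuantImage,
    mask: VOIMask,
    injected_activity_mbq: float,
    body_weight_kg: float,
) -> VOIQuant:
    """VOI statistics and mean SUV from a calibrated (Bq/ml) image.

    SUV normalizes the concentration by injected activity per body mass,
    assuming tissue density 1 g/ml:
    SUV = C [Bq/ml] / (A_inj [Bq] / m [g]).
    """
    if image.units != "Bq/ml":
        raise ConfigurationError(f"expected Bq/ml image, got {image.units!r}")
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise InvalidInputError("injected activity and body weight must be positive")
    _check_congruent(image, mask)
    values = image.voxels[mask.voxels]
    mean_c = float(values.mean())
    volume_ml = mask.n_voxels * image.voxel_volume_ml
    normalization = injected_activity_mbq * 1e6 / (body_weight_kg * 1000.0)  # Bq/g
    return VOIQuant(
        mean_concentration=mean_c,
        max_concentration=float(values.max()),
        volume=volume_ml,
        total_activity=mean_c * volume_ml,
        suv_mean=mean_c / normalization,
    )
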