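"""Seeded generators for every input the pipeline consumes.

The generators emulate a small Ac-225 PSMA therapy cohort: five patients
injected with ≈ 7.7 MBq, imaged at 24 and 48 h post-injection in three
photopeak windows (440 keV ²¹³Bi, 218 keV ²²¹Fr, 78 keV X-rays), with
CT-segmentable kidneys (ellipsoids, ≈ 247 ml) and spherical lesions
(≈ 23 ml), plus paired urine samples counted in a gamma counter.

Organ activities follow mono-exponential kinetics with window-specific
effective half-lives (kidneys ≈ 27 h for ²¹³Bi vs ≈ 24 h for ²²¹Fr — the
²²¹Fr kidney half-life is systematically shorter, as free ²¹³Bi accumulates
in kidney; lesions ≈ 38 h for both).  Urine ²¹³Bi counting series follow the
two-member Bateman ingrowth model with Poisson counting noise.

Every generator is a pure function of (scenario, seed): random streams are
spawned per component from the master seed, so regenerating one input does
not shift another's draws.  What the phantoms do NOT emulate: collimator
response, projection-domain noise, downscatter between windows, or
attenuation — images are "already reconstructed" quantitative volumes with
Gaussian system blur and voxel-wise Poisson counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .chain import LN2
from .errors import GeometryError, InvalidInputError
from .imaging import (
    WINDOW_BI213,
    WINDOW_FR221,
    WINDOW_XRAY,
    CalibrationFactor,
    EnergyWindow,
    QuantImage,
    VOIMask,
)
from .kinetics import TimeActivityPoint
from .urine import CountingSeries

#: stable component ids for spawning independent RNG streams
_STREAMS = {"cohort": 0, "image": 1, "tac": 2, "urine": 3}

WINDOWS = {"440": WINDOW_BI213, "218": WINDOW_FR221, "78": WINDOW_XRAY}


def component_rng(seed: int, component: str, *keys: int) -> np.random.Generator:
    """Independent generator for one (component, key...) slot of a scenario."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[component], *map(int, keys)])
    )


@dataclass(frozen=True)
class OrganTruth:
    """Ground-truth geometry and kinetics for one organ.

    ``a_t0`` / ``t_eff`` map window keys ("440", "218", "78") to the true
    amplitude (Bq) and effective half-life (h) of the organ's TAC in that
    window's surrogate nuclide.
    """

    name: str
    kind: str  # "kidney" or "lesion"
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    a_t0: dict[str, float]
    t_eff: dict[str, float]

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm)) / 1000.0

    def activity(self, window: str, time_h: float) -> float:
        return self.a_t0[window] * 2.0 ** (-time_h / self.t_eff[window])

    def concentration(self, window: str, time_h: float) -> float:
        """Bq/ml at a time point."""
        return self.activity(window, time_h) / self.volume_ml


@dataclass(frozen=True)
class PatientScenario:
    patient_id: str
    injected_mbq: float
    weight_kg: float
    organs: tuple[OrganTruth, ...]
    #: epoch (h p.i.) -> (A_Ac0, A_Bi0) urine concentrations at collection, Bq/ml
    urine_truth: dict[float, tuple[float, float]]


@dataclass(frozen=True)
class CohortScenario:
    """Full specification of a synthetic study, fixed by one master seed."""

    patients: tuple[PatientScenario, ...]
    seed: int
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: tuple[float, float, float] = (4.7952, 4.7952, 4.7952)
    image_times_h: tuple[float, ...] = (24.0, 48.0)
    #: true (cps/voxel) per (Bq/ml) per window
    calibration_truth: dict[str, float] = field(
        default_factory=lambda: {"440": 2.4e-4, "218": 3.0e-4, "78": 4.0e-4}
    )
    system_fwhm_mm: float = 14.0  # reconstructed-image resolution
    count_time_s: float = 3360.0  # effective counting time scaling Poisson noise
    background_fraction: float = 0.02  # soft-tissue background vs kidney conc.
    tac_cv: float = 0.10
    urine_efficiency: float = 0.2  # counts per decay in the 440 keV window
    urine_bin_h: float = 0.1
    urine_duration_h: float = 6.0
    phantom_concentration_bqml: float = 524.0
    phantom_volume_l: float = 8.7


def default_scenario(
    seed: int = 0,
    n_patients: int = 5,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
) -> CohortScenario:
    """A cohort mirroring the study scale.

    Five patients (7.7 ± 0.2 MBq injected), eight usable kidneys and nine
    lesions overall; kidney effective half-lives ≈ 27 h (²¹³Bi) and ≈ 24 h
    (²²¹Fr), lesion half-lives ≈ 38 h in both windows; kidney volumes
    ≈ 247 ml, lesion volumes ≈ 23 ml; urine ratios near 1 at 24 h drifting
    upward by ≈ 0.1 at 48 h.
    """
    rng = component_rng(seed, "cohort")
    fov_mm = np.array(grid_shape) * np.array((4.7952,) * 3)
    patients = []
    # lesion count pattern echoing the cohort shape: 9 lesions over 5 patients
    lesion_counts = [2, 2, 2, 2, 1][:n_patients]
    for i in range(n_patients):
        injected = float(np.clip(rng.normal(7.7, 0.2), 7.0, 8.4))
        weight = float(np.clip(rng.normal(85.0, 12.0), 55.0, 120.0))
        organs = []
        kidney_teff_bi = float(np.clip(rng.normal(27.0, 4.0), 15.0, 45.0))
        kidney_gap = float(rng.uniform(1.5, 4.5))  # Fr always shorter in kidney
        for side, xfrac in (("kidney_left", 0.38), ("kidney_right", 0.62)):
            teff_bi = kidney_teff_bi * float(rng.uniform(0.97, 1.03))
            teff_fr = teff_bi - kidney_gap
            radii = (28.0, 38.0, 55.0)  # ≈ 247 ml ellipsoid
            vol = 4 / 3 * np.pi * np.prod(radii) / 1000.0
            # kidney SUV ≈ 3.3 at 24 h in the 440 keV window
            suv24 = float(rng.normal(3.4, 0.5))
            conc24 = suv24 * injected * 1e6 / (weight * 1000.0)
            a24 = conc24 * vol
            a_t0 = {
                "440": a24 * 2.0 ** (24.0 / teff_bi),
                "218": a24 * 0.93 * 2.0 ** (24.0 / teff_fr),
                "78": a24 * 1.25 * 2.0 ** (24.0 / (teff_bi - kidney_gap - 0.8)),
            }
            organs.append(
                OrganTruth(
                    name=side,
                    kind="kidney",
                    center_mm=(
                        xfrac * fov_mm[0],
                        0.45 * fov_mm[1],
                        0.50 * fov_mm[2],
                    ),
                    radii_mm=radii,
                    a_t0=a_t0,
                    t_eff={
                        "440": teff_bi,
                        "218": teff_fr,
                        "78": max(teff_bi - kidney_gap - 0.8, 5.0),
                    },
                )
            )
        for j in range(lesion_counts[i]):
            teff = float(np.clip(rng.normal(38.0, 8.0), 12.0, 80.0))
            radius = float(rng.uniform(15.0, 22.0))  # ≈ 14–45 ml sphere
            vol = 4 / 3 * np.pi * radius**3 / 1000.0
            suv24 = float(rng.normal(5.0, 1.2))
            conc24 = suv24 * injected * 1e6 / (weight * 1000.0)
            a24 = conc24 * vol
            center = (
                (0.30 + 0.4 * j) * fov_mm[0],
                0.72 * fov_mm[1],
                (0.30 + 0.35 * j) * fov_mm[2],
            )
            organs.append(
                OrganTruth(
                    name=f"lesion_{j + 1}",
                    kind="lesion",
                    center_mm=center,
                    radii_mm=(radius, radius, radius),
                    a_t0={
                        "440": a24 * 2.0 ** (24.0 / teff),
                        "218": a24 * 0.92 * 2.0 ** (24.0 / (teff * rng.uniform(0.9, 1.1))),
                        "78": a24 * 1.1 * 2.0 ** (24.0 / (teff * rng.uniform(0.9, 1.1))),
                    },
                    t_eff={
                        "440": teff,
                        "218": teff * float(rng.uniform(0.95, 1.05)),
                        "78": teff * float(rng.uniform(0.9, 1.1)),
                    },
                )
            )
        ratio24 = float(rng.normal(0.98, 0.15))
        ratio48 = ratio24 + float(rng.normal(0.10, 0.08))
        ac24 = float(rng.uniform(60.0, 300.0))
        ac48 = float(rng.uniform(38.0, 115.0))
        patients.append(
            PatientScenario(
                patient_id=f"patient_{i + 1}",
                injected_mbq=injected,
                weight_kg=weight,
                organs=tuple(organs),
                urine_truth={
                    24.0: (ac24, max(ac24 * ratio24, 0.0)),
                    48.0: (ac48, max(ac48 * ratio48, 0.0)),
                },
            )
        )
    return CohortScenario(patients=tuple(patients), seed=seed, grid_shape=grid_shape)


def _ellipsoid_mask(grid_shape, voxel_size, center_mm, radii_mm) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(grid_shape, voxel_size)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    r = (
        ((xx - center_mm[0]) / radii_mm[0]) ** 2
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2
        + ((zz - center_mm[2]) / radii_mm[2]) ** 2
    )
    return r <= 1.0


def make_phantom_image(
    scenario: CohortScenario,
    patient: PatientScenario,
    time_point_h: float,
    window: str,
    noise: bool = True,
    blur: bool = True,
) -> tuple[QuantImage, dict[str, VOIMask], dict[str, float]]:
    """One patient's reconstructed volume at a time point and window.

    Organ concentrations follow each organ's surrogate kinetics; a Gaussian
    system blur and voxel-wise Poisson counting noise (applied in count
    space via the window's true calibration factor and counting time) give
    the image realistic statistics.  Returns the cps/voxel image, the truth
    masks and the truth concentrations (Bq/ml, pre-blur).

    Raises :class:`GeometryError` if organ volumes overlap.
    """
    if window not in WINDOWS:
        raise InvalidInputError(f"unknown window {window!r}")
    conc = np.zeros(scenario.grid_shape, dtype=float)
    occupied = np.zeros(scenario.grid_shape, dtype=bool)
    masks, truth_conc = {}, {}
    kidney_concs = [o.concentration(window, time_point_h) for o in patient.organs if o.kind == "kidney"]
    background = scenario.background_fraction * (np.mean(kidney_concs) if kidney_concs else 0.0)
    conc += background
    for organ in patient.organs:
        m = _ellipsoid_mask(scenario.grid_shape, scenario.voxel_size_mm, organ.center_mm, organ.radii_mm)
        if (m & occupied).any():
            raise GeometryError(f"organ {organ.name!r} overlaps another organ")
        occupied |= m
        c = organ.concentration(window, time_point_h)
        conc[m] = c
        masks[organ.name] = VOIMask(m, label=organ.name, origin="ct_based")
        truth_conc[organ.name] = c
    if blur and scenario.system_fwhm_mm > 0:
        sigma = [
            scenario.system_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / s
            for s in scenario.voxel_size_mm
        ]
        conc = ndimage.gaussian_filter(conc, sigma=sigma, mode="constant")
    calib = scenario.calibration_truth[window]
    cps = conc * calib
    if noise:
        rng = component_rng(
            scenario.seed, "image",
            _patient_index(scenario, patient), int(time_point_h), int(float(window)),
        )
        counts = rng.poisson(np.maximum(cps, 0.0) * scenario.count_time_s)
        cps = counts / scenario.count_time_s
    image = QuantImage(
        voxels=cps,
        voxel_size=scenario.voxel_size_mm,
        units="cps/voxel",
        time_post_injection=time_point_h,
        energy_window=WINDOWS[window],
    )
    return image, masks, truth_conc


def _patient_index(scenario: CohortScenario, patient: PatientScenario) -> int:
    for i, p in enumerate(scenario.patients):
        if p.patient_id == patient.patient_id:
            return i
    raise InvalidInputError(f"patient {patient.patient_id!r} not in scenario")


def make_calibration_phantom(
    scenario: CohortScenario,
    window: str,
    noise: bool = True,
) -> tuple[QuantImage, VOIMask, float]:
    """Uniform cylinder acquisition for the calibration workflow.

    The cylinder holds ``scenario.phantom_concentration_bqml`` (default
    524 Bq/ml over 8.7 l ≈ 4.56 MBq total) imaged with the window's true
    calibration factor; the returned VOI is a central cylinder safely away
    from blur-affected edges.  Also returns the true factor.
    """
    if window not in WINDOWS:
        raise InvalidInputError(f"unknown window {window!r}")
    shape, vs = scenario.grid_shape, scenario.voxel_size_mm
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, vs)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    fov = np.array(shape) * np.array(vs)
    radius_mm = 127.5  # 25.5 cm diameter
    volume_ml = scenario.phantom_volume_l * 1000.0
    height_mm = volume_ml * 1000.0 / (np.pi * radius_mm**2)
    height_mm = min(height_mm, 0.9 * fov[2])
    in_cyl = (
        ((xx - fov[0] / 2) ** 2 + (yy - fov[1] / 2) ** 2 <= radius_mm**2)
        & (np.abs(zz - fov[2] / 2) <= height_mm / 2)
    )
    conc = np.where(in_cyl, scenario.phantom_concentration_bqml, 0.0)
    if scenario.system_fwhm_mm > 0:
        sigma = [scenario.system_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / s for s in vs]
        conc = ndimage.gaussian_filter(conc, sigma=sigma, mode="constant")
    calib = scenario.calibration_truth[window]
    cps = conc * calib
    if noise:
        rng = component_rng(scenario.seed, "image", 999, int(float(window)))
        cps = rng.poisson(np.maximum(cps, 0) * scenario.count_time_s) / scenario.count_time_s
    central = (
        ((xx - fov[0] / 2) ** 2 + (yy - fov[1] / 2) ** 2 <= (0.6 * radius_mm) ** 2)
        & (np.abs(zz - fov[2] / 2) <= 0.3 * height_mm)
    )
    image = QuantImage(cps, vs, "cps/voxel", 0.0, WINDOWS[window])
    return image, VOIMask(central, label="phantom_voi"), calib


def simulate_voi_tac(
    a_t0: float,
    t_eff_h: float,
    times_h,
    cv: float,
    seed: int,
    stream_keys: tuple[int, ...] = (),
) -> list[TimeActivityPoint]:
    """Mono-exponential TAC samples with multiplicative lognormal noise.

    The log-noise has zero median so the two-point half-life estimator is
    median-unbiased; ``cv`` is the coefficient of variation of the
    multiplicative factor.
    """
    if cv < 0:
        raise InvalidInputError("cv must be non-negative")
    rng = component_rng(seed, "tac", *stream_keys)
    sigma_log = np.sqrt(np.log1p(cv**2))
    points = []
    for t in times_h:
        true = a_t0 * np.exp(-LN2 / t_eff_h * t)
        factor = np.exp(rng.normal(0.0, sigma_log)) if cv > 0 else 1.0
        points.append(TimeActivityPoint(time=float(t), activity=float(true * factor),
                                        sigma=float(true * cv) if cv > 0 else None))
    return points


def simulate_urine_series(
    a_ac0: float,
    a_bi0: float,
    efficiency: float,
    dt_h: float,
    duration_h: float,
    seed: int,
    collection_time_h: float = 24.0,
    sample_id: str = "sample",
    noise: bool = True,
    stream_keys: tuple[int, ...] = (),
) -> CountingSeries:
    """Gamma-counter ²¹³Bi counting series for one urine aliquot.

    Expected counts per bin = efficiency × decays of ²¹³Bi in the bin under
    the two-member Bateman model; each bin is an independent Poisson draw
    (or the exact expectation when ``noise=False``).
    """
    if not (0 < dt_h <= duration_h):
        raise InvalidInputError("need duration ≥ dt > 0")
    from .chain import default_chain

    chain = default_chain()
    lam_ac = chain["Ac-225"].decay_constant
    lam_bi = chain["Bi-213"].decay_constant
    t0 = np.arange(0.0, duration_h - dt_h / 2, dt_h)
    t1 = t0 + dt_h

    def integral(lam):
        return (np.exp(-lam * t0) - np.exp(-lam * t1)) / lam

    pref = lam_bi / (lam_bi - lam_ac)
    decays = 3600.0 * (
        a_ac0 * pref * (integral(lam_ac) - integral(lam_bi)) + a_bi0 * integral(lam_bi)
    )
    expected = efficiency * decays
    if noise:
        rng = component_rng(seed, "urine", *stream_keys)
        measured = rng.poisson(expected).astype(float)
    else:
        measured = expected
    return CountingSeries(
        sample_id=sample_id,
        collection_time=collection_time_h,
        times=t0,
        measured=measured,
        kind="counts",
        bin_width_h=dt_h,
        efficiency=efficiency,
    )


def scaled_scenario(scenario: CohortScenario, grid_shape: tuple[int, int, int]) -> CohortScenario:
    """The same cohort on a coarser grid (organ geometry rescaled with the
    field of view) — used to keep desk-scale runs fast."""
    old_fov = np.array(scenario.grid_shape) * np.array(scenario.voxel_size_mm)
    new_fov = np.array(grid_shape) * np.array(scenario.voxel_size_mm)
    scale = new_fov / old_fov
    patients = []
    for p in scenario.patients:
        organs = tuple(
            replace(o, center_mm=tuple(np.array(o.center_mm) * scale)) for o in p.organs
        )
        patients.append(replace(p, organs=organs))
    return replace(scenario, patients=tuple(patients), grid_shape=grid_shape)


def known_calibration(scenario: CohortScenario, window: str) -> CalibrationFactor:
    """The scenario's true calibration factor wrapped for the pipeline."""
    return CalibrationFactor(
        value=scenario.calibration_truth[window],
        energy_window=WINDOWS[window],
        provenance="scenario truth",
    )
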