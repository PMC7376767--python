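"""Synthetic phantoms and cohorts for the BAT quantification pipeline.

No imaging data ships with this package, so every pipeline stage is
exercised on generated stand-ins:

* :func:`make_phantom` builds one subject's co-registered volumes — complex
  multi-echo Dixon signals, an in-/out-of-phase magnitude pair, a PET
  activity map, and a CT map — from a simple geometric body: an ellipsoidal
  torso, two supraclavicular adipose depots, and low-fat-fraction BAT blobs
  inside the depots whose FDG hot spots are colocalized with the fat deficit
  (active BAT is both leaner and hotter). Ground truth is returned alongside
  the data.
* :func:`make_cohort` draws per-subject summary records (FF, SUV, age, BMI,
  CIT) from a bivariate model with a controllable standardized FF->SUV
  slope, emulating a cohort of young, lean male volunteers screened for
  cold-induced thermogenesis of at least 5%.

Noise models: Rician for MR magnitudes (complex Gaussian channel noise),
Gaussian for PET on the SUV scale, none for CT. All randomness derives from
one integer seed through `numpy.random.SeedSequence` spawning, so every
stream is independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dixon import EchoSeries, FatModel, SIX_PEAK, synthesize_echoes
from .pet import PetAcquisition
from .volumes import Grid, SegmentationMask, Volume3D

__all__ = [
    "COHORT2_ECHO_TIMES_MS",
    "COHORT1_ECHO_TIMES_MS",
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
]

#: Multi-echo protocol echo times (ms), 6 echoes.
COHORT2_ECHO_TIMES_MS = (1.09, 3.19, 5.29, 7.39, 9.49, 11.59)
#: Dual-echo protocol: out-of-phase / in-phase echo times (ms) at 3 T.
COHORT1_ECHO_TIMES_MS = (1.1, 2.2)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue, and noise parameters of one synthetic subject.

    Fat fractions are in per mille; the BAT blob mean must sit below the
    surrounding white-adipose mean (active BAT is leaner). ``mr_snr`` is the
    body-signal-to-noise ratio of the MR magnitudes (``None`` = noiseless);
    ``pet_noise_sd`` is Gaussian noise on the SUV scale.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_semiaxes_mm: tuple[float, float, float] = (56.0, 44.0, 42.0)
    depot_offset_mm: tuple[float, float, float] = (32.0, 8.0, 22.0)
    depot_semiaxes_mm: tuple[float, float, float] = (16.0, 13.0, 11.0)
    wat_ff_mean: float = 700.0
    wat_ff_sd: float = 20.0
    bat_ff_mean: float = 600.0
    bat_blob_count: int = 2
    bat_blob_radius_mm: float = 7.0
    suv_background: float = 0.4
    suv_hot_peak: float = 3.0
    mr_snr: float | None = 50.0
    pet_noise_sd: float = 0.05
    hu_fat_mean: float = -100.0
    hu_muscle_mean: float = 40.0
    muscle_ff: float = 80.0
    body_signal: float = 100.0
    field_map_amplitude_hz: float = 20.0
    r2star_s: float = 0.0
    fat_model: FatModel = SIX_PEAK
    field_strength_t: float = 3.0
    echo_times_ms: tuple[float, ...] = COHORT2_ECHO_TIMES_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bat_ff_mean >= self.wat_ff_mean:
            raise ValueError("BAT fat fraction must lie below the WAT mean")
        if self.wat_ff_sd < 0 or self.pet_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        half_extent = [sh * sp / 2 for sh, sp in zip(self.grid_shape, self.spacing_mm)]
        for off, semi, half in zip(self.depot_offset_mm,
                                   self.depot_semiaxes_mm, half_extent):
            if abs(off) + semi > half:
                raise ValueError("depot geometry extends outside the grid")
        for semi, half in zip(self.body_semiaxes_mm, half_extent):
            if semi > half:
                raise ValueError("body geometry extends outside the grid")


@dataclass
class PhantomTruth:
    """Noise-free ground truth kept alongside the generated data."""

    ff: Volume3D
    water: Volume3D
    fat: Volume3D
    suv: Volume3D
    body: SegmentationMask
    depot: SegmentationMask
    active: SegmentationMask
    anatomical: SegmentationMask
    summary: dict

    def __post_init__(self) -> None:
        if (self.active.values & ~self.depot.values).any():
            raise ValueError("truth masks must nest: active within depot")
        if (self.depot.values & ~self.body.values).any():
            raise ValueError("truth masks must nest: depot within body")


@dataclass
class Phantom:
    """One synthetic subject: acquisitions plus ground truth."""

    echoes: EchoSeries | None
    in_phase: Volume3D
    out_phase: Volume3D
    pet: Volume3D
    ct: Volume3D
    anatomical: SegmentationMask
    truth: PhantomTruth
    acquisition: PetAcquisition


def _ellipsoid(coords, center_mm, semiaxes_mm) -> np.ndarray:
    x, y, z = coords
    return (((x - center_mm[0]) / semiaxes_mm[0]) ** 2
            + ((y - center_mm[1]) / semiaxes_mm[1]) ** 2
            + ((z - center_mm[2]) / semiaxes_mm[2]) ** 2) <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec(),
                 acquisition: PetAcquisition | None = None,
                 with_echoes: bool = True) -> Phantom:
    """Generate one subject's co-registered synthetic volumes and truth.

    ``with_echoes=False`` skips the (comparatively expensive) complex
    multi-echo synthesis; every noise stream is spawned independently from
    the seed, so the remaining volumes are bit-identical either way.
    """
    grid = Grid(shape=spec.grid_shape, spacing=spec.spacing_mm)
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_tissue, rng_echo, rng_ipop, rng_pet = (
        np.random.default_rng(s) for s in ss.spawn(5))
    if acquisition is None:
        acquisition = PetAcquisition(injected_dose_mbq=75.0,
                                     body_weight_kg=75.0,
                                     uptake_interval_min=30.0)

    # world coordinates centered on the volume
    idx = np.indices(spec.grid_shape, dtype=float)
    center = [(sh - 1) * sp / 2 for sh, sp in zip(spec.grid_shape, spec.spacing_mm)]
    coords = [idx[a] * spec.spacing_mm[a] - center[a] for a in range(3)]

    body = _ellipsoid(coords, (0, 0, 0), spec.body_semiaxes_mm)
    ox, oy, oz = spec.depot_offset_mm
    depot = (_ellipsoid(coords, (-ox, oy, oz), spec.depot_semiaxes_mm)
             | _ellipsoid(coords, (ox, oy, oz), spec.depot_semiaxes_mm))
    depot &= body

    # BAT blobs: random centers inside each depot lobe, fully within it
    blob = np.zeros(spec.grid_shape, dtype=bool)
    blob_centers = []
    r = spec.bat_blob_radius_mm
    for side in (-1.0, 1.0):
        lobe_center = (side * ox, oy, oz)
        inner = tuple(max(s - r, 1.0) for s in spec.depot_semiaxes_mm)
        placed = 0
        for _ in range(200):
            if placed >= spec.bat_blob_count:
                break
            u = rng_geom.uniform(-1, 1, size=3)
            if (u ** 2).sum() > 1:
                continue
            c = tuple(lobe_center[a] + u[a] * inner[a] for a in range(3))
            blob |= _ellipsoid(coords, c, (r, r, r))
            blob_centers.append(c)
            placed += 1
    blob &= depot

    # fat-fraction field
    ff = np.zeros(spec.grid_shape)
    ff[body] = spec.muscle_ff
    wat = depot & ~blob
    ff[wat] = spec.wat_ff_mean + spec.wat_ff_sd * rng_tissue.standard_normal(
        int(wat.sum()))
    ff[blob] = spec.bat_ff_mean + spec.wat_ff_sd * rng_tissue.standard_normal(
        int(blob.sum()))
    ff = np.clip(ff, 0.0, 1000.0)

    signal = np.where(body, spec.body_signal, 0.0)
    fat = signal * ff / 1000.0
    water = signal - fat

    # smooth B0 field map: linear gradient across the volume
    span = max(coords[0].max(), 1.0)
    field_map = spec.field_map_amplitude_hz * coords[0] / span
    r2star = np.full(spec.grid_shape, spec.r2star_s)

    noisy = spec.mr_snr is not None and np.isfinite(spec.mr_snr)
    sigma = spec.body_signal / spec.mr_snr if noisy else 0.0

    echoes = None
    if with_echoes:
        echo_arr = synthesize_echoes(water, fat, spec.echo_times_ms,
                                     spec.fat_model, spec.field_strength_t,
                                     field_map_hz=field_map, r2star=r2star)
        if noisy:
            echo_arr = echo_arr + sigma * (
                rng_echo.standard_normal(echo_arr.shape)
                + 1j * rng_echo.standard_normal(echo_arr.shape))
        echoes = EchoSeries(
            echoes=[Volume3D(values=echo_arr[n], grid=grid, units="arbitrary")
                    for n in range(echo_arr.shape[0])],
            echo_times_ms=spec.echo_times_ms,
            field_strength_t=spec.field_strength_t,
        )

    ip = water + fat
    op = np.abs(water - fat)
    if noisy:
        # Rician magnitudes: complex channel noise, then modulus
        def rician(mag):
            re = mag + sigma * rng_ipop.standard_normal(mag.shape)
            im = sigma * rng_ipop.standard_normal(mag.shape)
            return np.hypot(re, im)
        ip = rician(ip)
        op = rician(op)

    # PET: hot spots riding on body background; amplitude linked to the
    # blobs' FF deficit so leaner blobs are hotter
    suv_true = np.where(body, spec.suv_background, 0.0)
    # linear link between the blobs' FF deficit and their peak uptake:
    # at the nominal 100 per-mille deficit the peak equals suv_hot_peak
    deficit = spec.wat_ff_mean - spec.bat_ff_mean
    amp = spec.suv_hot_peak * (0.5 + 0.5 * deficit / 100.0)
    sigma_mm = spec.bat_blob_radius_mm / 1.4
    for c in blob_centers:
        d2 = sum((coords[a] - c[a]) ** 2 for a in range(3))
        suv_true = suv_true + amp * np.exp(-d2 / (2 * sigma_mm ** 2))
    suv_true = np.where(body, suv_true, 0.0)
    suv_noisy = suv_true + spec.pet_noise_sd * rng_pet.standard_normal(
        spec.grid_shape) if spec.pet_noise_sd > 0 else suv_true.copy()
    suv_noisy = np.clip(suv_noisy, 0.0, None)
    dose_bq = acquisition.injected_dose_mbq * 1e6
    weight_g = acquisition.body_weight_kg * 1000.0
    activity = suv_noisy * (dose_bq / weight_g)

    # CT from tissue class
    ct = np.full(spec.grid_shape, -1000.0)
    ct[body] = spec.hu_muscle_mean
    ct[depot] = spec.hu_fat_mean

    # crude manual anatomical outline: depot dilated by two voxels
    from scipy import ndimage
    anat = ndimage.binary_dilation(
        depot, structure=ndimage.generate_binary_structure(3, 1), iterations=2)
    anat &= body

    active = depot & (suv_true >= 1.5)

    truth = PhantomTruth(
        ff=Volume3D(values=ff, grid=grid, units="per_mille"),
        water=Volume3D(values=water, grid=grid, units="arbitrary"),
        fat=Volume3D(values=fat, grid=grid, units="arbitrary"),
        suv=Volume3D(values=suv_true, grid=grid, units="g_per_ml"),
        body=SegmentationMask(values=body, grid=grid),
        depot=SegmentationMask(values=depot, grid=grid),
        active=SegmentationMask(values=active, grid=grid),
        anatomical=SegmentationMask(values=anat, grid=grid),
        summary={
            "wat_ff_mean": float(ff[wat].mean()) if wat.any() else np.nan,
            "bat_ff_mean": float(ff[blob].mean()) if blob.any() else np.nan,
            "depot_ff_mean": float(ff[depot].mean()) if depot.any() else np.nan,
            "active_suv_mean": float(suv_true[active].mean()) if active.any() else np.nan,
            "blob_centers_mm": blob_centers,
        },
    )
    return Phantom(
        echoes=echoes,
        in_phase=Volume3D(values=ip, grid=grid, units="arbitrary"),
        out_phase=Volume3D(values=op, grid=grid, units="arbitrary"),
        pet=Volume3D(values=activity, grid=grid, units="Bq_per_ml"),
        ct=Volume3D(values=ct, grid=grid, units="HU"),
        anatomical=truth.anatomical,
        truth=truth,
        acquisition=acquisition,
    )


# ---------------------------------------------------------------------------
# Cohort generator

@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters of one synthetic cohort.

    ``true_std_slope`` is the standardized regression slope of SUVmean on
    depot fat fraction (negative: leaner depots are more active). Centers
    and SDs put the simulated depot FF inside the plausible adult range
    (roughly 575–800 per mille) with SUVmean on the scale of cold-activated
    supraclavicular uptake.
    """

    n_subjects: int = 16
    cohort_id: int = 2
    true_std_slope: float = -0.65
    ff_center: float = 680.0
    ff_sd: float = 50.0
    suv_center: float = 2.2
    suv_sd: float = 0.7
    age_range: tuple[float, float] = (18.0, 40.0)
    bmi_range: tuple[float, float] = (19.0, 27.0)
    cit_mean: float = 9.0
    cit_sd: float = 3.0
    cit_floor: float = 5.0
    ee_warm_mean: float = 1700.0
    ee_warm_sd: float = 150.0
    sphere_contrast_mean: float = 55.0
    sphere_contrast_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        if abs(self.true_std_slope) > 1.0:
            raise ValueError("|standardized slope| cannot exceed 1")
        if self.cit_floor > self.cit_mean + 6 * self.cit_sd:
            raise ValueError("CIT floor is unreachable for this distribution")


def _truncated_normal(rng, mean, sd, floor, size):
    """Rejection-sampled normal draws constrained to >= floor."""
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw >= floor
        take = min(int(ok.sum()), size - n)
        out[n:n + take] = draw[ok][:take]
        n += take
    return out


def make_cohort(spec: CohortSpec = CohortSpec(),
                with_phantom_specs: bool = False):
    """Draw a cohort of subject records; optionally matching phantom specs.

    FF and SUV are generated from a standardized bivariate normal with the
    requested slope: z_suv = beta * z_ff + sqrt(1 - beta^2) * eps, then
    rescaled to the cohort's centers and SDs. When ``with_phantom_specs`` is
    true, each record is paired with a :class:`PhantomSpec` whose depot FF
    and hot-spot amplitude realise the drawn summary values.
    """
    from .stats import SubjectRecord, cit_percent

    ss = np.random.SeedSequence(spec.seed)
    rng, rng_phan = (np.random.default_rng(s) for s in ss.spawn(2))
    n = spec.n_subjects
    beta = spec.true_std_slope

    z_ff = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    z_suv = beta * z_ff + np.sqrt(max(0.0, 1.0 - beta ** 2)) * eps
    ff = np.clip(spec.ff_center + spec.ff_sd * z_ff, 1.0, 999.0)
    suv = np.clip(spec.suv_center + spec.suv_sd * z_suv, 0.05, None)

    age = rng.uniform(*spec.age_range, size=n)
    bmi = rng.uniform(*spec.bmi_range, size=n)
    height_m = rng.normal(1.78, 0.06, size=n)
    weight = bmi * height_m ** 2
    cit = _truncated_normal(rng, spec.cit_mean, spec.cit_sd, spec.cit_floor, n)
    ee_warm = np.clip(rng.normal(spec.ee_warm_mean, spec.ee_warm_sd, size=n),
                      800.0, None)
    ee_cold = ee_warm * (1.0 + cit / 100.0)
    contrast = np.clip(rng.normal(spec.sphere_contrast_mean,
                                  spec.sphere_contrast_sd, size=n), 5.0, None)

    records = []
    specs = []
    for i in range(n):
        ff_i = float(ff[i])
        records.append(SubjectRecord(
            id=f"c{spec.cohort_id}s{i + 1:02d}",
            cohort=spec.cohort_id,
            age=float(age[i]),
            bmi=float(bmi[i]),
            weight=float(weight[i]),
            ee_warm=float(ee_warm[i]),
            ee_cold=float(ee_cold[i]),
            cit=float(cit_percent(ee_warm[i], ee_cold[i])),
            ff_sc_total=ff_i,
            ff_active=max(ff_i - contrast[i], 0.0),
            ff_sphere_pos=max(ff_i - contrast[i], 0.0),
            ff_sphere_neg=min(ff_i + 0.0, 1000.0),
            suv_mean=float(suv[i]),
            bat_positive=True,
        ))
        if with_phantom_specs:
            specs.append(PhantomSpec(
                wat_ff_mean=ff_i,
                bat_ff_mean=max(ff_i - contrast[i], 50.0),
                suv_hot_peak=float(max(suv[i] * 1.5, 1.8)),
                seed=int(rng_phan.integers(0, 2 ** 31 - 1)),
            ))
    return (records, specs) if with_phantom_specs else (records, None)
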