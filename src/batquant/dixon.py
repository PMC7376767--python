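"""Water–fat separation and fat-fraction mapping from Dixon MRI.

Three reconstruction paths are provided:

* :func:`two_point_dixon` — in-phase/out-of-phase magnitude pairs
  (dual-echo protocols). Magnitude data cannot tell water-dominant from
  fat-dominant voxels, so the caller declares the dominant species.
* :func:`multiecho_dixon` — complex multi-echo data fitted voxelwise to the
  chemical-shift signal model with a B0 field map and optional R2* decay.
* :func:`fat_fraction` — normalises any water/fat pair into a fat-fraction
  map in per mille (0–1000‰), with a validity mask over voxels whose total
  signal clears a noise floor.

Signal model (TE in seconds, per voxel)::

    s(TE) = (W + F * c(TE)) * exp(i*2*pi*psi*TE) * exp(-R2* * TE)
    c(TE) = sum_p alpha_p * exp(i*2*pi*f_p*TE)

where ``f_p`` are the fat resonance offsets in Hz derived from the spectral
model's ppm shifts and the field strength, ``psi`` is the B0 off-resonance in
Hz and ``R2*`` the common transverse decay in 1/s. For fixed (psi, R2*) the
model is linear in the complex amplitudes (W, F); the fit is a variable
projection: a coarse search over (psi, R2*) with a closed-form linear solve,
refined by coordinate-wise parabolic steps, with a median-smoothed field map
between two passes to suppress water–fat swaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import Grid, SegmentationMask, Volume3D

__all__ = [
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "FatModel",
    "SINGLE_PEAK",
    "SIX_PEAK",
    "EchoSeries",
    "DixonFit",
    "FatFractionMap",
    "two_point_dixon",
    "fat_fraction",
    "multiecho_dixon",
    "synthesize_echoes",
]

#: Proton gyromagnetic ratio / 2*pi in MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577478518


@dataclass(frozen=True)
class FatModel:
    """Fat spectral model: resonance shifts (ppm vs water) and amplitudes."""

    peak_shifts_ppm: tuple[float, ...]
    peak_amplitudes: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.peak_shifts_ppm) != len(self.peak_amplitudes):
            raise ValueError("shifts and amplitudes differ in length")
        amps = np.asarray(self.peak_amplitudes, dtype=float)
        if np.any(amps < 0):
            raise ValueError("peak amplitudes must be nonnegative")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError("peak amplitudes must sum to 1")

    def peak_freqs_hz(self, field_strength_t: float) -> np.ndarray:
        """Fat peak offsets in Hz at the given field strength."""
        return (GYROMAGNETIC_RATIO_MHZ_PER_T * field_strength_t
                * np.asarray(self.peak_shifts_ppm, dtype=float))

    def fat_phasor(self, echo_times_ms: np.ndarray, field_strength_t: float) -> np.ndarray:
        """Complex fat signal c(TE) per echo, unit fat amplitude."""
        te_s = np.asarray(echo_times_ms, dtype=float) / 1000.0
        f = self.peak_freqs_hz(field_strength_t)
        a = np.asarray(self.peak_amplitudes, dtype=float)
        return (a[None, :] * np.exp(2j * np.pi * f[None, :] * te_s[:, None])).sum(axis=1)


#: Single methylene peak at -3.4 ppm; the classic Dixon assumption.
SINGLE_PEAK = FatModel(peak_shifts_ppm=(-3.40,), peak_amplitudes=(1.0,),
                       name="1peak")

#: Six-peak triglyceride spectrum in wide use for liver/adipose FF mapping
#: (relative weights renormalised to sum exactly to 1).
_SIX_PEAK_RAW = (0.087, 0.693, 0.128, 0.004, 0.039, 0.048)
SIX_PEAK = FatModel(
    peak_shifts_ppm=(-3.80, -3.40, -2.60, -1.94, -0.39, 0.60),
    peak_amplitudes=tuple(a / sum(_SIX_PEAK_RAW) for a in _SIX_PEAK_RAW),
    name="6peak",
)

FAT_MODELS = {"1peak": SINGLE_PEAK, "6peak": SIX_PEAK}


@dataclass
class EchoSeries:
    """Multi-echo Dixon acquisition: echo volumes plus timing metadata."""

    echoes: list[Volume3D]
    echo_times_ms: tuple[float, ...]
    field_strength_t: float = 3.0
    readout: str = "monopolar"

    def __post_init__(self) -> None:
        if len(self.echoes) < 2:
            raise ValueError("an echo series needs at least 2 echoes")
        if len(self.echoes) != len(self.echo_times_ms):
            raise ValueError("one echo time per echo required")
        te = np.asarray(self.echo_times_ms, dtype=float)
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        grid = self.echoes[0].grid
        for e in self.echoes[1:]:
            grid.require_match(e.grid, "echoes")

    @property
    def grid(self) -> Grid:
        return self.echoes[0].grid

    def stack(self) -> np.ndarray:
        """(n_echoes, *shape) array of echo values."""
        return np.stack([e.values for e in self.echoes], axis=0)

    @property
    def is_complex(self) -> bool:
        return any(np.iscomplexobj(e.values) for e in self.echoes)


@dataclass
class DixonFit:
    """Separated water/fat magnitudes plus optional field map and R2*."""

    water: Volume3D
    fat: Volume3D
    field_map_hz: Volume3D | None = None
    r2star: Volume3D | None = None
    residual: Volume3D | None = None

    def __post_init__(self) -> None:
        self.water.grid.require_match(self.fat.grid, "water and fat")
        if np.any(self.water.values < 0) or np.any(self.fat.values < 0):
            raise ValueError("water and fat must be nonnegative magnitudes")


@dataclass
class FatFractionMap:
    """Fat fraction in per mille with a validity mask."""

    ff: Volume3D
    valid_mask: SegmentationMask

    def __post_init__(self) -> None:
        self.ff.grid.require_match(self.valid_mask.grid, "FF map and valid mask")
        vals = self.ff.values[self.valid_mask.values]
        if vals.size and (vals.min() < 0 or vals.max() > 1000):
            raise ValueError("fat fraction out of the [0, 1000] per-mille range")


# ---------------------------------------------------------------------------
# Two-point (in-phase / out-of-phase) reconstruction

def two_point_dixon(in_phase: Volume3D, out_phase: Volume3D,
                    dominant: str = "fat") -> DixonFit:
    """Separate water and fat from an in-/out-of-phase magnitude pair.

    IP = W+F and OP = |W-F|, so (IP+OP)/2 recovers the dominant species and
    (IP-OP)/2 the other; ``dominant`` resolves the magnitude ambiguity.
    Negative values arising from noise are clamped to zero.
    """
    in_phase.grid.require_match(out_phase.grid, "in-phase and out-of-phase")
    if dominant not in ("water", "fat"):
        raise ValueError("dominant must be 'water' or 'fat'")
    ip = np.asarray(in_phase.values, dtype=float)
    op = np.asarray(out_phase.values, dtype=float)
    if np.any(ip < 0) or np.any(op < 0):
        raise ValueError("magnitude inputs must be nonnegative")
    big = np.clip((ip + op) / 2.0, 0.0, None)
    small = np.clip((ip - op) / 2.0, 0.0, None)
    if dominant == "water":
        w, f = big, small
    else:
        w, f = small, big
    return DixonFit(
        water=in_phase.with_values(w, units="arbitrary"),
        fat=in_phase.with_values(f, units="arbitrary"),
    )


def fat_fraction(fit: DixonFit, noise_floor: float | None = None) -> FatFractionMap:
    """FF = 1000 * F / (W + F) in per mille where total signal clears the floor.

    ``noise_floor`` defaults to 5% of the 99th percentile of W+F; pass 0 to
    keep every voxel with strictly positive total signal.
    """
    w = fit.water.values.astype(float)
    f = fit.fat.values.astype(float)
    total = w + f
    if noise_floor is None:
        noise_floor = 0.05 * np.percentile(total, 99)
    valid = total > max(noise_floor, 0.0)
    ff = np.zeros_like(total)
    np.divide(1000.0 * f, total, out=ff, where=valid)
    ff = np.clip(ff, 0.0, 1000.0)
    ff[~valid] = 0.0
    return FatFractionMap(
        ff=fit.water.with_values(ff, units="per_mille"),
        valid_mask=SegmentationMask(values=valid, grid=fit.water.grid),
    )


# ---------------------------------------------------------------------------
# Multi-echo chemical-shift reconstruction

def synthesize_echoes(water: np.ndarray, fat: np.ndarray,
                      echo_times_ms, fat_model: FatModel,
                      field_strength_t: float = 3.0,
                      field_map_hz: np.ndarray | float = 0.0,
                      r2star: np.ndarray | float = 0.0) -> np.ndarray:
    """Forward model: complex echo signals from water/fat amplitudes.

    Returns an (n_echoes, ...) complex array; the inverse of
    :func:`multiecho_dixon` on noiseless data.
    """
    te_s = np.asarray(echo_times_ms, dtype=float) / 1000.0
    c = fat_model.fat_phasor(echo_times_ms, field_strength_t)
    w = np.asarray(water, dtype=float)
    f = np.asarray(fat, dtype=float)
    psi = np.asarray(field_map_hz, dtype=float)
    r2 = np.asarray(r2star, dtype=float)
    shape = (len(te_s),) + np.broadcast_shapes(w.shape, f.shape, psi.shape, r2.shape)
    out = np.empty(shape, dtype=complex)
    for n, te in enumerate(te_s):
        out[n] = (w + f * c[n]) * np.exp((2j * np.pi * psi - r2) * te)
    return out


def _solve_wf(signals: np.ndarray, te_s: np.ndarray, c: np.ndarray,
              psi: np.ndarray, r2: np.ndarray):
    """Closed-form complex least squares for (W, F) at fixed (psi, R2*).

    signals: (n_echoes, N); psi, r2: (N,) arrays or scalars. Returns complex
    amplitudes w, f of shape (N,) and the residual sum of squares.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    # per-echo modulation g_n = exp((i·2π·psi − R2*)·TE_n), shape (n, N)
    g = np.exp((2j * np.pi * psi - r2)[None, :] * te_s[:, None])
    # two-column complex LS: design columns g_n and c_n·g_n
    wts = (g.real ** 2 + g.imag ** 2)  # |g_n|^2
    a11 = wts.sum(axis=0)
    a12 = (c[:, None] * wts).sum(axis=0)
    a22 = ((np.abs(c) ** 2)[:, None] * wts).sum(axis=0)
    b1 = (np.conj(g) * signals).sum(axis=0)
    b2 = (np.conj(c)[:, None] * np.conj(g) * signals).sum(axis=0)
    det = a11 * a22 - (a12.real ** 2 + a12.imag ** 2)
    det = np.where(det == 0, 1e-300, det)
    w = (a22 * b1 - a12 * b2) / det
    f = (a11 * b2 - np.conj(a12) * b1) / det
    fitted = (w[None, :] + f[None, :] * c[:, None]) * g
    rss = (np.abs(signals - fitted) ** 2).sum(axis=0)
    return w, f, rss


def _residual_grid(signals, te_s, c, psi_grid, r2_grid):
    """Best (psi, r2) per voxel over a Cartesian grid; returns indices."""
    nvox = signals.shape[1]
    best_rss = np.full(nvox, np.inf)
    best_psi = np.zeros(nvox)
    best_r2 = np.zeros(nvox)
    for psi in psi_grid:
        for r2 in r2_grid:
            _, _, rss = _solve_wf(signals, te_s, c,
                                  np.full(nvox, psi), np.full(nvox, r2))
            better = rss < best_rss
            best_rss[better] = rss[better]
            best_psi[better] = psi
            best_r2[better] = r2
    return best_psi, best_r2, best_rss


def _local_refine(signals, te_s, c, psi, r2, psi_step, r2_step,
                  iters=16, fit_r2star=True):
    """Joint shrinking-grid minimisation of the VARPRO residual.

    Field map and R2* are coupled in the residual, so both are refined
    together: each iteration evaluates a small (psi, r2) neighbourhood
    around the per-voxel best, keeps the minimum, and halves the steps.
    """
    nvox = signals.shape[1]
    offsets = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    step_p = float(psi_step)
    step_r = float(r2_step) if fit_r2star else 0.0
    r2_offsets = offsets if fit_r2star and r2_step > 0 else np.array([0.0])
    for _ in range(iters):
        best_rss = np.full(nvox, np.inf)
        best_psi = psi.copy()
        best_r2 = r2.copy()
        for dp in offsets:
            cand_psi = psi + dp * step_p
            for dr in r2_offsets:
                cand_r2 = np.clip(r2 + dr * step_r, 0.0, None)
                _, _, rss = _solve_wf(signals, te_s, c, cand_psi, cand_r2)
                better = rss < best_rss
                best_rss[better] = rss[better]
                best_psi[better] = cand_psi[better]
                best_r2[better] = cand_r2[better]
        psi, r2 = best_psi, best_r2
        step_p *= 0.5
        step_r *= 0.5
    return psi, r2


def multiecho_dixon(series: EchoSeries, fat_model: FatModel = SIX_PEAK,
                    fit_r2star: bool = False,
                    field_map_range_hz: float = 150.0,
                    field_map_step_hz: float = 4.0,
                    r2star_max: float = 300.0,
                    smooth_field_map: bool = True,
                    fit_mask=None) -> DixonFit:
    """Voxelwise chemical-shift water–fat fit on complex multi-echo data.

    Requires >= 3 echoes (>= 4 with ``fit_r2star``). The field map from a
    first fitting pass is median-filtered (3x3x3) and the fit repeated in a
    narrow band around the smoothed map, which suppresses isolated water–fat
    swaps without region growing. ``fit_mask`` (a SegmentationMask or boolean
    array) restricts the fit to a region of interest; voxels outside get
    zero water/fat and should be excluded downstream via the FF valid mask.
    """
    n_echo = len(series.echoes)
    n_params = 4 if fit_r2star else 3  # W, F, psi (+ R2*)
    if n_echo < n_params:
        raise ValueError(
            f"need at least {n_params} echoes for this fit, got {n_echo}")
    if not series.is_complex:
        raise ValueError("multi-echo fitting requires complex echo data")

    grid = series.grid
    shape = grid.shape
    te_s = np.asarray(series.echo_times_ms, dtype=float) / 1000.0
    c = fat_model.fat_phasor(series.echo_times_ms, series.field_strength_t)
    signals_full = series.stack().reshape(n_echo, -1).astype(complex)
    if fit_mask is not None:
        sel_mask = np.asarray(getattr(fit_mask, "values", fit_mask), dtype=bool)
        if sel_mask.shape != shape:
            raise ValueError("fit_mask shape does not match the echo grid")
        sel = np.flatnonzero(sel_mask.ravel())
    else:
        sel = np.arange(signals_full.shape[1])
    signals = signals_full[:, sel]
    nvox = signals.shape[1]

    # pass 1: coarse grid + refinement
    psi_grid = np.arange(-field_map_range_hz, field_map_range_hz + 1e-9,
                         field_map_step_hz)
    if 0.0 not in psi_grid:
        psi_grid = np.sort(np.append(psi_grid, 0.0))
    r2_grid = np.linspace(0.0, r2star_max, 7) if fit_r2star else np.array([0.0])
    psi, r2, _ = _residual_grid(signals, te_s, c, psi_grid, r2_grid)
    r2_coarse = (r2_grid[1] - r2_grid[0]) if fit_r2star else 0.0
    psi, r2 = _local_refine(signals, te_s, c, psi, r2,
                            psi_step=field_map_step_hz,
                            r2_step=r2_coarse, fit_r2star=fit_r2star)

    if smooth_field_map:
        # pass 2: restart near the median-smoothed field map
        psi_vol = np.zeros(shape)
        psi_vol.ravel()[sel] = psi
        psi_s = ndimage.median_filter(psi_vol, size=3).ravel()[sel]
        psi2, r22 = _local_refine(signals, te_s, c, psi_s, r2,
                                  psi_step=field_map_step_hz,
                                  r2_step=r2_coarse / 2,
                                  fit_r2star=fit_r2star)
        # keep the restart only where it does not worsen the residual
        _, _, rss1 = _solve_wf(signals, te_s, c, psi, r2)
        _, _, rss2 = _solve_wf(signals, te_s, c, psi2, r22)
        take = rss2 <= rss1 + 1e-12
        psi = np.where(take, psi2, psi)
        r2 = np.where(take, r22, r2)

    w_c, f_c, rss = _solve_wf(signals, te_s, c, psi, r2)
    # common-phase removal: project both amplitudes onto the dominant phase
    w = np.abs(w_c)
    f = np.abs(f_c)

    def vol(arr, units="arbitrary"):
        full = np.zeros(int(np.prod(shape)))
        full[sel] = arr
        return Volume3D(values=full.reshape(shape), grid=grid, units=units)

    return DixonFit(
        water=vol(w),
        fat=vol(f),
        field_map_hz=vol(psi),
        r2star=vol(r2) if fit_r2star else None,
        residual=vol(rss),
    )
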