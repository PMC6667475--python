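"""Membrane observables: grid thickness, lateral diffusion, bending rigidity.

Three quantities characterise a near-planar bilayer here:

* **Thickness** — the separation between the phosphate (or fallback
  reference-bead) centres of mass of the two leaflets, averaged on an
  in-plane grid (40×40 by default).
* **Lateral diffusion coefficient D_L** — from the 2-D Einstein relation
  MSD(τ) = 4·D_L·τ applied to lipid centre-of-mass motion in the membrane
  plane, with time-origin averaging.
* **Bending rigidity K_C** — from the thermal undulation spectrum of the
  mid-plane height field, which continuum (Helfrich–Canham) elasticity
  predicts to follow ⟨|h_q|²⟩ = k_BT / (A·(K_C·q⁴ + σ·q²)) for projected
  area A, rigidity K_C and tension σ.

Internal units: Å, ps, k_BT. D_L is reported in μm² s⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trajectory_io import (FrameSeries, LeafletLabels, UPPER, LOWER,
                            reference_bead_indices, _fill_periodic_nearest)
from .units import A2_PER_PS_TO_UM2_PER_S

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# block averaging

def block_statistics(values: Sequence[float], n_blocks: int = 5
                     ) -> tuple[float, float]:
    """Mean and block-averaged standard error of a per-frame scalar series.

    The series is split into ``n_blocks`` contiguous equal blocks (trailing
    remainder frames are dropped); stderr = SD(block means)/√n_blocks.
    """
    v = np.asarray(values, dtype=np.float64)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if v.size < n_blocks:
        raise ValueError(f"need ≥ {n_blocks} values for {n_blocks} blocks")
    usable = (v.size // n_blocks) * n_blocks
    block_means = v[:usable].reshape(n_blocks, -1).mean(axis=1)
    stderr = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return float(v.mean()), stderr


# ---------------------------------------------------------------------------
# thickness

@dataclass
class ThicknessResult:
    per_frame_grid: np.ndarray      # (T, nx, ny), NaN where a cell lacks beads
    per_frame_mean: np.ndarray      # (T,)
    mean: float
    stderr: float
    grid_dims: tuple[int, int]


def grid_thickness(series: FrameSeries, labels: LeafletLabels,
                   nx: int = 40, ny: int = 40,
                   n_blocks: int = 5) -> ThicknessResult:
    """Leaflet-to-leaflet thickness on an nx×ny in-plane grid.

    Per cell and frame: thickness = COM z of upper-leaflet reference beads −
    COM z of lower-leaflet reference beads. Cells missing beads in either
    leaflet are excluded from the frame mean. The trajectory mean is the mean
    of per-frame means; its error is block-averaged when enough frames exist.
    """
    lipid_ids, ref = reference_bead_indices(series.particles)
    T = series.n_frames
    grids = np.full((T, nx, ny), np.nan)
    frame_means = np.empty(T)
    sparse_frames = 0
    worst_empty = 0.0
    for t in range(T):
        lab = labels.labels[min(t, labels.labels.shape[0] - 1)]
        up = ref[lab == UPPER]
        lo = ref[lab == LOWER]
        if up.size == 0 or lo.size == 0:
            raise ValueError(f"frame {t}: a leaflet is empty")
        box = series.boxes[t]
        zu = _cell_mean_z(series.coords[t], up, box, nx, ny)
        zl = _cell_mean_z(series.coords[t], lo, box, nx, ny)
        thick = zu - zl
        grids[t] = thick
        ok = np.isfinite(thick)
        if ok.mean() < 0.5:
            sparse_frames += 1
            worst_empty = max(worst_empty, 1 - ok.mean())
        frame_means[t] = np.nanmean(thick)
    if sparse_frames:
        logger.warning(
            "%d of %d frames have >50%% empty thickness cells (worst %.0f%%);"
            " empty cells are excluded from frame means", sparse_frames, T,
            100 * worst_empty)
    if T >= n_blocks:
        mean, stderr = block_statistics(frame_means, n_blocks)
    else:
        mean = float(frame_means.mean())
        stderr = float(frame_means.std(ddof=1) / np.sqrt(T)) if T > 1 else 0.0
    return ThicknessResult(per_frame_grid=grids, per_frame_mean=frame_means,
                           mean=mean, stderr=stderr, grid_dims=(nx, ny))


def _cell_mean_z(coords: np.ndarray, idx: np.ndarray, box: np.ndarray,
                 nx: int, ny: int) -> np.ndarray:
    ix = np.floor(np.mod(coords[idx, 0], box[0]) / box[0] * nx).astype(int) % nx
    iy = np.floor(np.mod(coords[idx, 1], box[1]) / box[1] * ny).astype(int) % ny
    cell = ix * ny + iy
    sums = np.bincount(cell, weights=coords[idx, 2], minlength=nx * ny)
    counts = np.bincount(cell, minlength=nx * ny)
    out = np.full(nx * ny, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out.reshape(nx, ny)


# ---------------------------------------------------------------------------
# MSD and diffusion

@dataclass
class MSDCurve:
    lag_times: np.ndarray   # ps
    msd: np.ndarray         # Å²
    n_pairs: np.ndarray     # (lipids × time origins) per lag


@dataclass
class DiffusionEstimate:
    D_L: float              # μm² s⁻¹
    stderr: float           # μm² s⁻¹
    fit_window: tuple[float, float]   # ps
    r_squared: float
    negative_slope: bool = False


def lipid_com_trajectories(series: FrameSeries,
                           species_filter: Optional[set] = None) -> np.ndarray:
    """(T, n_lipids, 3) centre-of-mass trajectory of each (filtered) lipid."""
    p = series.particles
    ids = p.lipid_ids
    if species_filter is not None:
        sp = p.lipid_species()
        keep = np.isin(sp, list(species_filter))
        ids = ids[keep]
        if ids.size == 0:
            raise ValueError(f"species filter {sorted(species_filter)} matches no lipid")
    T = series.n_frames
    com = np.empty((T, ids.size, 3))
    # equal bead masses: COM = mean over beads
    member = {lid: np.nonzero(p.lipid_id == lid)[0] for lid in ids}
    for k, lid in enumerate(ids):
        com[:, k, :] = series.coords[:, member[lid], :].mean(axis=1)
    return com


def lateral_msd(series: FrameSeries, species_filter: Optional[set] = None,
                max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-origin-averaged lateral (x,y) MSD of lipid centres of mass.

    The series must already be unwrapped in x and y and uniformly sampled in
    time. Uses the FFT autocorrelation identity for O(T log T) per lipid.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dt = np.diff(series.times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time spacing; MSD requires a constant stride")
    com = lipid_com_trajectories(series, species_filter)[:, :, :2]
    T = com.shape[0]
    max_lag = max(1, int(np.floor(max_lag_fraction * (T - 1))))
    msd = np.zeros(max_lag + 1)
    for k in range(com.shape[1]):
        msd += _msd_fft(com[:, k, :])[:max_lag + 1]
    msd /= com.shape[1]
    n_origins = T - np.arange(max_lag + 1)
    return MSDCurve(lag_times=np.arange(max_lag + 1) * float(dt[0]),
                    msd=msd, n_pairs=n_origins * com.shape[1])


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """MSD over all time origins for one particle, r of shape (T, d)."""
    T = r.shape[0]
    s2 = (r ** 2).sum(axis=1)
    # autocorrelation via zero-padded FFT, summed over dimensions
    n_fft = 1 << (2 * T - 1).bit_length()
    acf = np.zeros(T)
    for d in range(r.shape[1]):
        f = np.fft.rfft(r[:, d], n_fft)
        acf += np.fft.irfft(f * np.conj(f), n_fft)[:T]
    sumsq = np.concatenate(([0.0], s2, [0.0]))
    q = 2 * s2.sum()
    msd = np.empty(T)
    for m in range(T):
        q -= sumsq[m] + sumsq[T - m + 1]
        msd[m] = q / (T - m) - 2 * acf[m] / (T - m)
    msd[0] = 0.0
    return msd


def default_fit_window(msd: MSDCurve, lo: float = 0.1, hi: float = 0.5
                       ) -> tuple[float, float]:
    """Fit window spanning 10%–50% of the maximum available lag (default)."""
    tmax = msd.lag_times[-1]
    return (lo * tmax, hi * tmax)


def fit_diffusion(msd: MSDCurve,
                  fit_window: Optional[tuple[float, float]] = None
                  ) -> DiffusionEstimate:
    """Least-squares line MSD = 4·D·τ + b over the window; D in μm² s⁻¹."""
    if fit_window is None:
        fit_window = default_fit_window(msd)
    t_lo, t_hi = fit_window
    sel = (msd.lag_times >= t_lo) & (msd.lag_times <= t_hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    x = msd.lag_times[sel]
    y = msd.msd[sel]
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    fitted = A @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    slope_se = float(np.sqrt(cov[0, 0]))
    negative = slope < 0
    if negative:
        logger.warning("negative MSD slope; reporting D_L = 0")
    d_a2ps = max(slope, 0.0) / 4.0
    return DiffusionEstimate(D_L=d_a2ps * A2_PER_PS_TO_UM2_PER_S,
                             stderr=slope_se / 4.0 * A2_PER_PS_TO_UM2_PER_S,
                             fit_window=(float(t_lo), float(t_hi)),
                             r_squared=r2, negative_slope=negative)


# ---------------------------------------------------------------------------
# height field & undulation spectrum

@dataclass
class HeightFieldSeries:
    grids: np.ndarray      # (T, M, M), per-frame mean removed
    cell_size: float       # Å
    box_area: float        # Å²


@dataclass
class UndulationSpectrum:
    q: np.ndarray          # effective |q| per bin, Å⁻¹
    s_q: np.ndarray        # ⟨|h_q|²⟩, Å⁴ (continuum convention)
    n_q: np.ndarray        # modes per bin
    n_frames: int
    box_area: float


@dataclass
class RigidityEstimate:
    K_C: float             # k_BT
    sigma: float           # k_BT Å⁻²
    stderr_KC: float       # k_BT
    q_range: tuple[float, float]


def height_field(series: FrameSeries, labels: LeafletLabels,
                 grid_m: int) -> HeightFieldSeries:
    """Mid-plane height field h(x,y,t) on a grid_m×grid_m in-plane grid.

    Per cell the mid-plane height is (upper-leaflet reference COM z +
    lower-leaflet COM z)/2; empty cells are filled from periodic nearest
    neighbours; per-frame mean height is removed.
    """
    lipid_ids, ref = reference_bead_indices(series.particles)
    if ref.size / grid_m ** 2 < 1.0:
        raise ValueError(
            f"grid {grid_m}×{grid_m} leaves <1 bead per cell on average; "
            "use a coarser grid")
    box0 = series.boxes[0]
    if not np.isclose(box0[0], box0[1], rtol=1e-6):
        raise ValueError("height field requires a square in-plane box")
    T = series.n_frames
    grids = np.empty((T, grid_m, grid_m))
    for t in range(T):
        lab = labels.labels[min(t, labels.labels.shape[0] - 1)]
        up = ref[lab == UPPER]
        lo = ref[lab == LOWER]
        box = series.boxes[t]
        zu = _cell_mean_z(series.coords[t], up, box, grid_m, grid_m)
        zl = _cell_mean_z(series.coords[t], lo, box, grid_m, grid_m)
        h = _fill_periodic_nearest(0.5 * (zu + zl))
        grids[t] = h - h.mean()
    return HeightFieldSeries(grids=grids, cell_size=float(box0[0]) / grid_m,
                             box_area=float(box0[0] * box0[1]))


def fluctuation_spectrum(fields: HeightFieldSeries,
                         min_frames: int = 10) -> UndulationSpectrum:
    """Radially binned undulation spectrum ⟨|h_q|²⟩ of the height field.

    Continuum normalisation: ⟨|h_q|²⟩ = ⟨|ĥ_mn|²⟩ · cell_area² / box_area,
    with ĥ the raw (unnormalised) 2-D DFT. Modes are binned by |q| with bin
    width Δq = 2π/L; each bin's reported q is q_eff = ⟨q⁻⁴⟩^(−1/4) over member
    modes so a q⁻⁴ spectrum is unbiased under binning; q = 0 is excluded.
    """
    T, M, _ = fields.grids.shape
    if T < min_frames:
        raise ValueError(f"need ≥{min_frames} frames for a spectrum")
    L = fields.cell_size * M
    cell_area = fields.cell_size ** 2
    power = np.zeros((M, M))
    for t in range(T):
        H = np.fft.fft2(fields.grids[t])
        power += np.abs(H) ** 2
    power /= T
    s_mode = power * cell_area ** 2 / fields.box_area

    dq = 2 * np.pi / L
    freq = np.fft.fftfreq(M, d=1.0 / M)  # integer mode numbers
    qx = freq[:, None] * dq
    qy = freq[None, :] * dq
    qmag = np.sqrt(qx ** 2 + qy ** 2)
    bins = np.rint(qmag / dq).astype(int)
    nonzero = bins > 0
    n_bins = bins[nonzero].max() + 1
    s_q, q_eff, n_q = [], [], []
    for b in range(1, n_bins):
        sel = nonzero & (bins == b)
        if not np.any(sel):
            continue
        s_q.append(s_mode[sel].mean())
        q_eff.append(np.mean(qmag[sel] ** -4.0) ** -0.25)
        n_q.append(int(sel.sum()))
    if len(s_q) < 3:
        raise ValueError("fewer than 3 nonzero-q bins; grid too coarse")
    return UndulationSpectrum(q=np.array(q_eff), s_q=np.array(s_q),
                              n_q=np.array(n_q), n_frames=T,
                              box_area=fields.box_area)


def fit_bending_rigidity(spec: UndulationSpectrum, box_area: float,
                         q_max: float, include_tension: bool = True
                         ) -> RigidityEstimate:
    """Weighted least-squares Helfrich fit of the undulation spectrum.

    Fits 1/(s_q·A) = K_C·q⁴ + σ·q² (energies in k_BT) over bins with
    q ≤ q_max. Weights follow the χ²-distributed mode variance
    (var(s_q) ≈ s_q²/n_eff). K_C error is a leave-one-bin-out jackknife.
    """
    sel = spec.q <= q_max
    if sel.sum() < 4:
        raise ValueError("need ≥4 spectrum bins with q ≤ q_max")
    q = spec.q[sel]
    y = 1.0 / (spec.s_q[sel] * box_area)
    # each Hermitian mode pair contributes one independent sample per frame
    n_eff = np.maximum(spec.n_q[sel] * spec.n_frames / 2.0, 1.0)
    w = n_eff / y ** 2

    def solve(qv, yv, wv):
        X = np.column_stack([qv ** 4, qv ** 2]) if include_tension \
            else qv[:, None] ** 4
        sw = np.sqrt(wv)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], yv * sw, rcond=None)
        kc = float(coef[0])
        sig = float(coef[1]) if include_tension else 0.0
        return kc, sig

    kc, sigma = solve(q, y, w)
    if kc <= 0:
        raise ValueError("spectrum inconsistent with Helfrich form "
                         "(fitted K_C ≤ 0)")
    # jackknife over bins
    n = q.size
    kcs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        kcs[i], _ = solve(q[keep], y[keep], w[keep])
    stderr = float(np.sqrt((n - 1) / n * np.sum((kcs - kcs.mean()) ** 2)))
    return RigidityEstimate(K_C=kc, sigma=sigma, stderr_KC=stderr,
                            q_range=(float(q.min()), float(q.max())))


def default_q_max(thickness: float) -> float:
    """Standard protrusion cutoff: q_max = 2π / (2 × bilayer thickness)."""
    return 2 * np.pi / (2 * thickness)
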