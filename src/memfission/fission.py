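"""Tubulation and fission analysis of membrane pulling trajectories.

A constant perpendicular force applied to a ~30 Å-radius patch of a planar
bilayer extrudes a tube. Three complementary measurements characterise what
follows:

* the **elongation trace** L(t): height of the pulled patch's headgroup
  centre of mass above the base-membrane mid-plane;
* a **changepoint test** on L(t): fission releases the tube, so the trace
  shows a sudden inflection to a steeper slope — detected by exhaustive
  two-segment continuous piecewise-linear least squares with an F-test;
* **topological detection**: single-linkage clustering of headgroup beads
  under periodic boundary conditions; fission has occurred once the bead
  cloud splits into two persistent clusters (and, on the way there, the
  tube's minimum neck radius shrinks toward zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .trajectory_io import Frame, FrameSeries, ParticleTable, \
    reference_bead_indices
from .units import PS_TO_NS

logger = logging.getLogger(__name__)


@dataclass
class PatchSelection:
    lipid_ids: np.ndarray
    center: tuple[float, float]   # Å
    radius: float                 # Å

    def __post_init__(self) -> None:
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.int64)
        if self.lipid_ids.size == 0:
            raise ValueError("empty patch selection")


@dataclass
class ElongationTrace:
    times: np.ndarray       # ns
    elongation: np.ndarray  # Å


@dataclass
class InflectionResult:
    detected: bool
    time: float = np.nan                  # ns
    elongation_at_inflection: float = np.nan  # Å
    slope_pre: float = np.nan             # Å/ns
    slope_post: float = np.nan            # Å/ns
    significance: float = np.nan          # F statistic of the model comparison


@dataclass
class FissionEvent:
    frame: int
    time: float             # ns
    mode: str               # topological_separation | neck_closure
    neck_series: Optional[np.ndarray] = None


def select_patch(frame: Frame, particles: ParticleTable,
                 center: tuple[float, float], radius: float = 30.0
                 ) -> PatchSelection:
    """Lipids whose headgroup reference bead lies within ``radius`` of
    ``center`` by periodic in-plane distance; both leaflets included."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ids, ref = reference_bead_indices(particles)
    box = frame.box[:2]
    d = frame.coords[ref, :2] - np.asarray(center)
    d -= np.round(d / box) * box
    sel = np.hypot(d[:, 0], d[:, 1]) <= radius
    if not np.any(sel):
        raise ValueError("no lipids within the patch radius")
    return PatchSelection(lipid_ids=ids[sel], center=tuple(center),
                          radius=radius)


def elongation_trace(series: FrameSeries, patch: PatchSelection,
                     base_region: np.ndarray) -> ElongationTrace:
    """Per-frame patch headgroup-COM height above the base mid-plane, Å vs ns.

    ``base_region`` is the array of lipid ids that make up the flat base
    membrane (everything excluding the tube).
    """
    ids, ref = reference_bead_indices(series.particles)
    pos = {int(l): i for i, l in enumerate(ids)}
    try:
        patch_idx = ref[[pos[int(l)] for l in patch.lipid_ids]]
    except KeyError as exc:
        raise ValueError(f"patch lipid {exc} absent from the series") from exc
    base = np.asarray(base_region, dtype=np.int64)
    if base.size == 0:
        raise ValueError("base region is empty")
    base_idx = ref[[pos[int(l)] for l in base]]
    elong = (series.coords[:, patch_idx, 2].mean(axis=1)
             - series.coords[:, base_idx, 2].mean(axis=1))
    return ElongationTrace(times=series.times * PS_TO_NS, elongation=elong)


def elongation_rate(trace: ElongationTrace,
                    window: Optional[tuple[float, float]] = None
                    ) -> tuple[float, float]:
    """Least-squares slope (Å/ns) of the trace over a time window, with SE."""
    t, y = trace.times, trace.elongation
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 3:
            raise ValueError("fewer than 3 points in the rate window")
        t, y = t[sel], y[sel]
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(t.size - 2, 1)
    cov = (resid @ resid / dof) * np.linalg.inv(A.T @ A)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def detect_inflection(trace: ElongationTrace, min_slope_ratio: float = 1.5,
                      alpha: float = 0.01, min_segment: int = 3
                      ) -> InflectionResult:
    """Changepoint test for the fission inflection of an elongation trace.

    Fits the continuous hinge model y = a + b·t + c·(t−τ)₊ at every interior
    candidate breakpoint τ and compares the best fit against a single line
    with an F-test (Bonferroni-corrected over candidates, to control the
    selection effect of scanning for the best τ). A breakpoint is accepted
    when the corrected test passes at ``alpha`` AND the post/pre slope ratio
    is at least ``min_slope_ratio`` — fission releases the tube, so the trace
    steepens.
    """
    t = np.asarray(trace.times, dtype=np.float64)
    y = np.asarray(trace.elongation, dtype=np.float64)
    n = t.size
    if n < 20:
        raise ValueError("need at least 20 points for changepoint detection")
    # single-line fit
    A1 = np.column_stack([np.ones(n), t])
    c1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    sse1 = float(np.sum((y - A1 @ c1) ** 2))

    best = None
    candidates = range(min_segment, n - min_segment)
    n_cand = len(candidates)
    for i in candidates:
        tau = t[i]
        hinge = np.maximum(t - tau, 0.0)
        A2 = np.column_stack([np.ones(n), t, hinge])
        c2, *_ = np.linalg.lstsq(A2, y, rcond=None)
        sse2 = float(np.sum((y - A2 @ c2) ** 2))
        if best is None or sse2 < best[0]:
            best = (sse2, tau, c2)
    sse2, tau, c2 = best
    slope_pre = float(c2[1])
    slope_post = float(c2[1] + c2[2])
    # two-segment model has 4 params (a, b, c, τ); line has 2
    df2 = n - 4
    if df2 <= 0 or sse2 <= 0:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = ((sse1 - sse2) / 2.0) / (sse2 / df2)
        p = stats.f.sf(f_stat, 2, df2)
    significant = p * n_cand < alpha
    ratio_ok = (slope_pre > 0 and slope_post / slope_pre >= min_slope_ratio) \
        or (slope_pre <= 0 < slope_post)
    if significant and ratio_ok:
        y_at = float(np.interp(tau, t, y))
        return InflectionResult(detected=True, time=float(tau),
                                elongation_at_inflection=y_at,
                                slope_pre=slope_pre, slope_post=slope_post,
                                significance=float(f_stat))
    return InflectionResult(detected=False, significance=float(f_stat),
                            slope_pre=slope_pre, slope_post=slope_post)


# ---------------------------------------------------------------------------
# topological fission detection

def _cluster_count(coords: np.ndarray, box: np.ndarray, cutoff: float
                   ) -> np.ndarray:
    """Single-linkage cluster labels at ``cutoff`` under periodic boundaries."""
    wrapped = np.mod(coords, box)
    # cKDTree's periodic metric requires points strictly inside [0, box)
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = coords.shape[0]
    if pairs.size == 0:
        return np.arange(n)
    data = np.ones(pairs.shape[0])
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def detect_fission_topology(series: FrameSeries, cutoff: Optional[float] = None,
                            min_cluster_fraction: float = 0.05,
                            persistence: int = 3) -> Optional[FissionEvent]:
    """First frame where the headgroup bead cloud splits into ≥2 clusters.

    Clusters come from single-linkage clustering with a periodic distance
    cutoff (default 1.5 × the median nearest-neighbour distance in frame 0).
    The event must persist for ``persistence`` consecutive frames and each of
    the two largest clusters must hold at least ``min_cluster_fraction`` of
    the lipids.
    """
    ids, ref = reference_bead_indices(series.particles)
    n = ref.size
    box0 = series.boxes[0]
    if cutoff is None:
        wrapped = np.mod(series.coords[0, ref], box0)
        wrapped = np.where(wrapped >= box0, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box0)
        dist, _ = tree.query(wrapped, k=2)
        cutoff = 1.5 * float(np.median(dist[:, 1]))
    else:
        wrapped = np.mod(series.coords[0, ref], box0)
        wrapped = np.where(wrapped >= box0, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box0)
        dist, _ = tree.query(wrapped, k=2)
        if cutoff < float(dist[:, 1].min()):
            raise ValueError("cutoff is below the minimum bead spacing")
    min_size = max(1, int(np.ceil(min_cluster_fraction * n)))
    run_start = None
    run_len = 0
    for t in range(series.n_frames):
        labels = _cluster_count(series.coords[t, ref], series.boxes[t], cutoff)
        sizes = np.sort(np.bincount(labels))[::-1]
        split = sizes.size >= 2 and sizes[1] >= min_size
        if split:
            if run_start is None:
                run_start = t
            run_len += 1
            if run_len >= persistence:
                return FissionEvent(frame=run_start,
                                    time=float(series.times[run_start]) * PS_TO_NS,
                                    mode="topological_separation")
        else:
            run_start, run_len = None, 0
    return None


def neck_profile(series: FrameSeries, slab: float = 10.0,
                 base_region: Optional[np.ndarray] = None,
                 base_offset: float = 25.0) -> np.ndarray:
    """Per-frame minimum neck radius (Å) of a tubulated membrane.

    Headgroup beads above the base membrane (z > base mid-plane +
    ``base_offset``) are binned into slabs of ``slab`` Å along the membrane
    normal; per slab the radius is the RMS in-plane distance from the slab
    centroid (for beads on a circle this equals the circle radius); the
    per-frame minimum over slabs is returned. ``base_region`` (lipid ids)
    pins the base mid-plane; without it the median bead height is used, which
    assumes most lipids sit in the base membrane.
    """
    ids, ref = reference_bead_indices(series.particles)
    base_idx = None
    if base_region is not None:
        pos = {int(l): i for i, l in enumerate(ids)}
        base_idx = ref[[pos[int(l)] for l in np.asarray(base_region)]]
    out = np.full(series.n_frames, np.nan)
    for t in range(series.n_frames):
        z = series.coords[t, ref, 2]
        if base_idx is not None:
            base_mid = float(series.coords[t, base_idx, 2].mean())
        else:
            base_mid = np.median(z)
        sel = z > base_mid + base_offset
        if not np.any(sel):
            continue
        zs = z[sel]
        xy = series.coords[t, ref, :2][sel]
        edges = np.arange(zs.min(), zs.max() + slab, slab)
        if edges.size < 2:
            edges = np.array([zs.min(), zs.max() + 1e-9])
        idx = np.clip(np.digitize(zs, edges) - 1, 0, edges.size - 2)
        radii = []
        for b in range(edges.size - 1):
            m = idx == b
            if m.sum() < 3:
                continue
            centroid = xy[m].mean(axis=0)
            radii.append(float(np.sqrt(np.mean(np.sum((xy[m] - centroid) ** 2,
                                                      axis=1)))))
        if not radii:
            raise ValueError(f"frame {t}: no populated slabs along the tube")
        out[t] = min(radii)
    return out
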