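"""Synthetic fixtures with known ground truth for every analysis stage.

These generators are kinematic/statistical, not dynamical: ground truth
(thickness, diffusion coefficient, bending rigidity, free-energy profile,
fission time) is imposed by construction, which is what makes parameter
recovery a legitimate oracle for the estimators in this package. They stand
in for cluster-scale coarse-grained MD trajectories (16,900-lipid bilayers)
that cannot be regenerated at desk scale.

Every generator is a pure function of (parameters, seed) and attaches a
:class:`SyntheticSpec` record of its ground truth; tests read truth from that
record, never from constants duplicated in test code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trajectory_io import FrameSeries, ParticleTable
from .pmf import UmbrellaWindow
from .membrane import HeightFieldSeries
from .units import UM2_PER_S_TO_A2_PER_PS, NS_TO_PS


@dataclass
class SyntheticSpec:
    """Ground-truth record emitted alongside every fixture."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"generator": self.generator, "seed": self.seed,
                "parameters": dict(self.parameters)}


def _single_bead_table(n_lipids: int, species: str = "DOPC",
                       role: str = "phosphate") -> ParticleTable:
    return ParticleTable(
        particle_id=np.arange(n_lipids),
        lipid_id=np.arange(n_lipids),
        species=np.full(n_lipids, species, dtype=object),
        bead_role=np.full(n_lipids, role, dtype=object))


# ---------------------------------------------------------------------------
# flat bilayer (thickness oracle)

def gen_flat_bilayer(n_per_leaflet: int, box_xy: float = 400.0,
                     thickness: float = 38.0, z_jitter: float = 0.0,
                     seed: int = 0, n_frames: int = 1,
                     dt: float = 100.0) -> FrameSeries:
    """Two leaflets of single-bead phosphate lipids at z = ±thickness/2.

    In-plane positions are uniform random and fixed over frames; z-jitter is
    redrawn per frame. Generator leaflet tags (+1 upper / −1 lower) are stored
    in provenance.
    """
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_leaflet
    xy = rng.uniform(0, box_xy, size=(n, 2))
    z0 = np.concatenate([np.full(n_per_leaflet, thickness / 2),
                         np.full(n_per_leaflet, -thickness / 2)])
    tags = np.concatenate([np.ones(n_per_leaflet, dtype=np.int8),
                           -np.ones(n_per_leaflet, dtype=np.int8)])
    box_z = max(4 * thickness, 100.0)
    coords = np.empty((n_frames, n, 3))
    for t in range(n_frames):
        z = z0 + (rng.normal(0.0, z_jitter, size=n) if z_jitter > 0 else 0.0)
        coords[t, :, 0] = xy[:, 0]
        coords[t, :, 1] = xy[:, 1]
        coords[t, :, 2] = z + box_z / 2
    spec = SyntheticSpec("flat_bilayer", seed, {
        "n_per_leaflet": n_per_leaflet, "box_xy": box_xy,
        "thickness": thickness, "z_jitter": z_jitter, "n_frames": n_frames})
    return FrameSeries(times=np.arange(n_frames) * dt, coords=coords,
                       boxes=np.tile([box_xy, box_xy, box_z], (n_frames, 1)),
                       particles=_single_bead_table(n),
                       provenance={"spec": spec.as_dict(),
                                   "leaflet_tags": tags})


# ---------------------------------------------------------------------------
# Helfrich membrane (bending-rigidity oracle)

def gen_helfrich_membrane(L: float = 400.0, grid_m: int = 40,
                          K_C: float = 25.0, sigma: float = 0.0,
                          thickness: float = 38.0, n_frames: int = 1000,
                          seed: int = 0, dt: float = 100.0,
                          make_series: bool = True
                          ) -> tuple[Optional[FrameSeries], HeightFieldSeries]:
    """Thermally fluctuating periodic height field with known K_C and σ.

    Per frame, independent complex Gaussian Fourier modes with the
    equipartition variance ⟨|h_q|²⟩ = k_BT / (L²·(K_C·q⁴ + σ·q²)) (continuum
    convention, k_BT = 1) are synthesised to a real height grid; one phosphate
    bead per cell per leaflet is placed at the cell centre at z = h ± t/2.
    """
    if K_C <= 0:
        raise ValueError("K_C must be positive")
    if grid_m % 2:
        raise ValueError("grid_m must be even")
    rng = np.random.default_rng(seed)
    M = grid_m
    dq = 2 * np.pi / L
    freq = np.fft.fftfreq(M, d=1.0 / M)
    qx = freq[:, None] * dq
    qy = freq[None, :] * dq
    q2 = qx ** 2 + qy ** 2
    energy = K_C * q2 ** 2 + sigma * q2
    nonzero = q2 > 0
    if np.any(energy[nonzero] <= 0):
        raise ValueError("K_C·q⁴ + σ·q² ≤ 0 for some mode: unstable Hamiltonian")
    target_h2 = np.zeros_like(energy)
    target_h2[nonzero] = 1.0 / (L ** 2 * energy[nonzero])
    # |DFT coefficient|² target = continuum ⟨|h_q|²⟩ · M⁴ / L²; white real
    # noise FFT'd gives Hermitian modes with ⟨|W|²⟩ = M², so scale by
    # sqrt(target_H2)/M.
    scale = np.sqrt(target_h2 * M ** 4 / L ** 2) / M

    grids = np.empty((n_frames, M, M))
    for t in range(n_frames):
        W = np.fft.fft2(rng.standard_normal((M, M)))
        h = np.fft.ifft2(W * scale).real
        grids[t] = h - h.mean()
    fields = HeightFieldSeries(grids=grids, cell_size=L / M, box_area=L * L)

    spec = SyntheticSpec("helfrich_membrane", seed, {
        "L": L, "grid_m": grid_m, "K_C": K_C, "sigma": sigma,
        "thickness": thickness, "n_frames": n_frames})

    series = None
    if make_series:
        centers = (np.arange(M) + 0.5) * (L / M)
        cx, cy = np.meshgrid(centers, centers, indexing="ij")
        n = 2 * M * M
        box_z = max(4 * thickness, 200.0)
        coords = np.empty((n_frames, n, 3))
        flat_x = cx.ravel()
        flat_y = cy.ravel()
        for t in range(n_frames):
            h = grids[t].ravel()
            coords[t, :M * M, 0] = flat_x
            coords[t, :M * M, 1] = flat_y
            coords[t, :M * M, 2] = h + thickness / 2 + box_z / 2
            coords[t, M * M:, 0] = flat_x
            coords[t, M * M:, 1] = flat_y
            coords[t, M * M:, 2] = h - thickness / 2 + box_z / 2
        tags = np.concatenate([np.ones(M * M, dtype=np.int8),
                               -np.ones(M * M, dtype=np.int8)])
        series = FrameSeries(times=np.arange(n_frames) * dt, coords=coords,
                             boxes=np.tile([L, L, box_z], (n_frames, 1)),
                             particles=_single_bead_table(n),
                             provenance={"spec": spec.as_dict(),
                                         "leaflet_tags": tags})
    return series, fields


# ---------------------------------------------------------------------------
# Brownian lipids (diffusion oracle)

def gen_brownian_lipids(n: int = 1000, D: float = 50.0, dt: float = 100.0,
                        n_frames: int = 500, box: float = 400.0,
                        seed: int = 0) -> FrameSeries:
    """2-D Brownian single-bead lipids with known D (μm² s⁻¹), wrapped in x,y.

    Per-axis increments are Gaussian with variance 2·D·dt. The true unwrapped
    (x,y) trajectories are stored in provenance["true_coords"].
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    d_int = D * UM2_PER_S_TO_A2_PER_PS   # Å² / ps
    sd = np.sqrt(2 * d_int * dt)
    start = rng.uniform(0, box, size=(1, n, 2))
    steps = rng.normal(0.0, sd, size=(n_frames - 1, n, 2)) if sd > 0 \
        else np.zeros((n_frames - 1, n, 2))
    true = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    box_z = 100.0
    coords = np.zeros((n_frames, n, 3))
    coords[:, :, :2] = np.mod(true, box)
    coords[:, :, 2] = box_z / 2
    spec = SyntheticSpec("brownian_lipids", seed, {
        "n": n, "D": D, "dt": dt, "n_frames": n_frames, "box": box})
    return FrameSeries(times=np.arange(n_frames) * dt, coords=coords,
                       boxes=np.tile([box, box, box_z], (n_frames, 1)),
                       particles=_single_bead_table(n),
                       provenance={"spec": spec.as_dict(), "true_coords": true})


# ---------------------------------------------------------------------------
# umbrella windows (WHAM oracle)

def analytic_pmf(tag: str, params: dict):
    """Analytic free-energy function U(z) in k_BT for a named profile family."""
    if tag == "harmonic":
        kappa, z0 = params["kappa"], params["z0"]
        return lambda z: kappa * (z - z0) ** 2
    if tag == "double_well":
        # two Gaussian wells of depth ≈ height sunk into a flat plateau:
        # bounded edge slopes, so every window remains resolvable
        h = params["height"]
        z1, z2 = params["z1"], params["z2"]
        s = params.get("well_sd", 3.0)
        return lambda z: h * (1.0
                              - np.exp(-((z - z1) ** 2) / (2 * s ** 2))
                              - np.exp(-((z - z2) ** 2) / (2 * s ** 2)))
    if tag == "piecewise":
        zk = np.asarray(params["z_knots"], dtype=float)
        gk = np.asarray(params["g_knots"], dtype=float)
        return lambda z: np.interp(z, zk, gk)
    raise ValueError(f"unknown analytic PMF tag {tag!r}")


def gen_umbrella_samples(pmf: str, pmf_params: dict,
                         centers: Sequence[float], k: float,
                         n_per_window: int = 5000, t_span: float = 100.0,
                         seed: int = 0, grid_step: float = 0.01
                         ) -> tuple[list[UmbrellaWindow], SyntheticSpec]:
    """Exact Boltzmann samples from U(z) + ½k(z−c)² for each window.

    ``k`` is in internal units (k_BT Å⁻²). Sampling is by inverse CDF on a
    ``grid_step`` Å grid — i.i.d. by construction, so WHAM tests see no
    equilibration or autocorrelation confounds. Timestamps are spread
    uniformly over ``t_span`` ns.
    """
    u_fn = analytic_pmf(pmf, pmf_params)
    rng = np.random.default_rng(seed)
    sigma = 1.0 / np.sqrt(k) if k > 0 else 5.0
    lo = min(centers) - 6 * sigma
    hi = max(centers) + 6 * sigma
    z = np.arange(lo, hi + grid_step, grid_step)
    u_z = np.asarray(u_fn(z), dtype=float)
    if not np.all(np.isfinite(u_z)):
        raise ValueError("PMF not finite on the sampling support")
    windows = []
    times = (np.arange(n_per_window) + 1) / n_per_window * t_span * NS_TO_PS
    for c in centers:
        logp = -(u_z + 0.5 * k * (z - c) ** 2)
        p = np.exp(logp - logp.max())
        if p.sum() <= 0:
            raise ValueError(f"sampling density vanishes for window at {c} Å")
        # piecewise-constant density over grid cells; CDF at cell edges keeps
        # the sampler unbiased (a half-cell shift would tilt stiff-spring
        # window means measurably)
        edges = np.concatenate([z - grid_step / 2, [z[-1] + grid_step / 2]])
        cdf = np.concatenate([[0.0], np.cumsum(p)])
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_per_window), cdf, edges)
        windows.append(UmbrellaWindow(center=float(c), force_constant=k,
                                      samples=samples, times=times))
    spec = SyntheticSpec("umbrella_samples", seed, {
        "pmf": pmf, "pmf_params": dict(pmf_params),
        "centers": list(map(float, centers)), "k": k,
        "n_per_window": n_per_window, "t_span": t_span})
    return windows, spec


# ---------------------------------------------------------------------------
# tubulation / fission movie

def gen_tubulation_movie(base_lipids: int = 15000,
                         tube_lipids: Optional[int] = None,
                         rate_pre: float = 8.75, rate_post: float = 25.0,
                         fission_time: Optional[float] = 80.0,
                         neck_schedule: str = "linear",
                         noise_sd: float = 0.5, n_frames: int = 120,
                         seed: int = 0, box_xy: float = 700.0,
                         tube_radius: float = 20.0,
                         cap_radius: float = 28.0,
                         bead_spacing: Optional[float] = None,
                         frame_dt_ns: float = 1.0) -> FrameSeries:
    """Kinematic point-cloud movie of a membrane growing a tubule that severs.

    The membrane mid-surface is represented by one headgroup bead per lipid.
    A planar annular base surrounds a cylindrical tube whose tip height
    follows the scripted two-slope L(t): rate_pre Å/ns before fission and
    rate_post after (the released tube travels faster). Shaft beads occupy a
    fixed lattice for the final tube length and are extruded from the base
    reservoir as the tube grows, so bead spacing never exceeds
    ``bead_spacing``. The neck (a waist at 50 Å above the base) follows
    ``neck_schedule`` ('linear' shrinks the waist radius to 0 at
    fission_time; 'constant' keeps it open); at fission the head detaches and
    translates at rate_post while neck beads retract into the base.

    Provenance carries the full script: elongation L(t), neck radius series,
    patch (cap) and base lipid ids, and the fission frame index.
    """
    if rate_pre < 0 or rate_post < 0:
        raise ValueError("rates must be non-negative")
    t_ns = np.arange(n_frames) * frame_dt_ns
    if fission_time is not None and not (0 < fission_time < t_ns[-1]):
        raise ValueError("fission_time must lie inside the movie time span")
    rng = np.random.default_rng(seed)

    # scripted tip height
    if fission_time is None:
        L_t = rate_pre * t_ns
        L_f = L_t[-1]
    else:
        L_f = rate_pre * fission_time
        L_t = np.where(t_ns < fission_time, rate_pre * t_ns,
                       L_f + rate_post * (t_ns - fission_time))
    inner = tube_radius + 2.0
    outer = box_xy / 2 - 20.0
    annulus_area = np.pi * (outer ** 2 - inner ** 2)

    # Tube lattice spacing defaults to the base lattice constant, solved
    # self-consistently (the base lattice holds a reservoir slot per shaft
    # bead, so its constant depends on the shaft count and vice versa).
    # Matching the two spacings keeps every link of the connected membrane
    # comfortably inside the 1.5×median-NN clustering cutoff.
    def shaft_counts(dz: float) -> tuple[int, int]:
        n_rings = int(np.ceil(max(L_f, dz) / dz))
        n_ring = max(3, int(round(2 * np.pi * tube_radius / dz)))
        return n_rings, n_ring

    if bead_spacing is None:
        bead_spacing = 4.0
        for _ in range(4):
            nr, nc = shaft_counts(bead_spacing)
            bead_spacing = 0.98 * np.sqrt(
                annulus_area / (base_lipids + nr * nc))
    n_rings, n_ring = shaft_counts(bead_spacing)
    n_shaft = n_rings * n_ring
    if tube_lipids is None:
        tube_lipids = n_shaft + max(
            10, int(round(np.pi * cap_radius ** 2 / bead_spacing ** 2)))
    n_cap = tube_lipids - n_shaft
    if n_cap < 10:
        raise ValueError(
            f"tube_lipids={tube_lipids} too few to tile a {L_f:.0f} Å "
            f"cylinder at {bead_spacing:.2f} Å spacing ({n_shaft} shaft "
            "beads needed plus ≥10 cap beads)")
    ring_z = (np.repeat(np.arange(1, n_rings + 1), n_ring)
              * bead_spacing)                       # absolute lattice heights
    ring_theta = np.tile(np.linspace(0, 2 * np.pi, n_ring, endpoint=False),
                         n_rings)
    ring_theta += rng.uniform(0, 2 * np.pi / n_ring, size=ring_theta.size)

    # cap: sunflower disk
    i = np.arange(n_cap)
    cap_r = cap_radius * np.sqrt((i + 0.5) / n_cap)
    cap_th = i * 2.399963229728653

    # Base annulus on one jittered square lattice holding base lipids AND a
    # reservoir slot per not-yet-extruded shaft bead. A lattice (unlike
    # random placement) stays a single cluster under the 1.5×median-NN
    # single-linkage cutoff, and parking reservoir beads on the same lattice
    # keeps the frame-0 spacing — which anchors that cutoff — uniform. As
    # the tube extrudes, the base thins to a random-site-diluted lattice,
    # still far above the site-percolation threshold.
    # 2% margin so edge effects cannot leave the lattice short of slots
    a = 0.98 * np.sqrt(annulus_area / (base_lipids + n_shaft))
    cx = cy = box_xy / 2
    g1d = np.arange(-outer, outer + a, a)
    gx, gy = np.meshgrid(g1d, g1d, indexing="ij")
    gx = gx.ravel() + rng.normal(0.0, 0.08 * a, gx.size)
    gy = gy.ravel() + rng.normal(0.0, 0.08 * a, gy.size)
    rr = np.hypot(gx, gy)
    keep = (rr >= inner) & (rr <= outer)
    sx_all = cx + gx[keep]
    sy_all = cy + gy[keep]
    n_sites = sx_all.size
    if n_sites < base_lipids + n_shaft:
        raise ValueError("annulus too small for the requested lipid counts")
    order = rng.permutation(n_sites)
    res_slots = order[:n_shaft]
    base_slots = order[n_shaft:n_shaft + base_lipids]
    base_x, base_y = sx_all[base_slots], sy_all[base_slots]
    res_x, res_y = sx_all[res_slots], sy_all[res_slots]
    n_base = base_x.size

    # neck waist radius over time
    if fission_time is None or neck_schedule == "constant":
        neck_r = np.full(n_frames, tube_radius)
    elif neck_schedule == "linear":
        neck_r = tube_radius * np.clip(1.0 - t_ns / fission_time, 0.0, 1.0)
    else:
        raise ValueError(f"unknown neck schedule {neck_schedule!r}")

    neck_center, neck_halfwidth = 50.0, 40.0
    z0 = 120.0                       # base plane height inside the box
    max_z = L_t.max() + z0 + 50.0
    box_z = max_z + 100.0

    n_total = n_base + n_shaft + n_cap
    coords = np.empty((n_frames, n_total, 3))
    fission_frame = None
    for fi, t in enumerate(t_ns):
        severed = fission_time is not None and t >= fission_time
        if severed and fission_frame is None:
            fission_frame = fi
        # base
        coords[fi, :n_base, 0] = base_x
        coords[fi, :n_base, 1] = base_y
        coords[fi, :n_base, 2] = z0
        # shaft: extruded if lattice height ≤ current length, else reservoir;
        # after severance only the head (above the neck region) remains a tube
        if severed:
            extruded = ring_z >= 80.0
            shift = rate_post * (t - fission_time)
        else:
            extruded = ring_z <= L_t[fi]
            shift = 0.0
        sx = np.empty(n_shaft)
        sy = np.empty(n_shaft)
        sz = np.empty(n_shaft)
        # waist profile: radius dips to neck_r at the neck centre
        dip = np.clip(1.0 - np.abs(ring_z - neck_center) / neck_halfwidth,
                      0.0, 1.0)
        radii = tube_radius - (tube_radius - neck_r[fi]) * dip
        sx[extruded] = cx + radii[extruded] * np.cos(ring_theta[extruded])
        sy[extruded] = cy + radii[extruded] * np.sin(ring_theta[extruded])
        sz[extruded] = z0 + ring_z[extruded] + shift
        res = ~extruded
        sx[res] = res_x[res]
        sy[res] = res_y[res]
        sz[res] = z0
        coords[fi, n_base:n_base + n_shaft, 0] = sx
        coords[fi, n_base:n_base + n_shaft, 1] = sy
        coords[fi, n_base:n_base + n_shaft, 2] = sz
        # cap at the scripted tip height
        coords[fi, n_base + n_shaft:, 0] = cx + cap_r * np.cos(cap_th)
        coords[fi, n_base + n_shaft:, 1] = cy + cap_r * np.sin(cap_th)
        coords[fi, n_base + n_shaft:, 2] = z0 + L_t[fi]
    coords += rng.normal(0.0, noise_sd, size=coords.shape)

    spec = SyntheticSpec("tubulation_movie", seed, {
        "base_lipids": base_lipids, "tube_lipids": tube_lipids,
        "rate_pre": rate_pre, "rate_post": rate_post,
        "fission_time": fission_time, "neck_schedule": neck_schedule,
        "noise_sd": noise_sd, "n_frames": n_frames, "box_xy": box_xy,
        "tube_radius": tube_radius, "cap_radius": cap_radius,
        "bead_spacing": bead_spacing, "frame_dt_ns": frame_dt_ns})
    provenance = {
        "spec": spec.as_dict(),
        "elongation_script": L_t,
        "times_ns": t_ns,
        "neck_radius_script": neck_r,
        "fission_frame": fission_frame,
        "patch_lipid_ids": np.arange(n_base + n_shaft, n_total),
        "base_lipid_ids": np.arange(n_base),
    }
    return FrameSeries(times=t_ns * NS_TO_PS, coords=coords,
                       boxes=np.tile([box_xy, box_xy, box_z], (n_frames, 1)),
                       particles=_single_bead_table(n_total),
                       provenance=provenance)
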