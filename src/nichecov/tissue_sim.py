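"""Synthetic tissues with known cell-type affinities and expression.

Ground-truth spatial architectures are generated by 2D Langevin dynamics of
particles interacting through pairwise Lennard-Jones potentials

    V(r) = 4 eps_ab [ (sigma/r)^12 - (sigma/r)^6 ],  truncated at rc,

where the well depth eps_ab encodes the affinity between cell types a and
b: short-range repulsion mimics physical cell boundaries, the attractive
tail preferential co-localisation. Particles start at non-overlapping
uniform random positions in a periodic box and are thermostatted at reduced
temperature T with a BAOAB Langevin integrator; the final configuration is
the tissue snapshot. On top of a snapshot, negative-binomial expression
with type-specific marker programs and an optional planted cross-type
coupling of latent factor activities can be synthesised, together with a
matched (spatially uncoupled) reference dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from numba import njit

from .core_io import CountMatrix, ReferenceDataset, SpatialDataset

__all__ = [
    "SimulationConfig",
    "TissueSnapshot",
    "SyntheticExpressionConfig",
    "SimTruth",
    "lj_potential",
    "simulate_tissue",
    "scenario_config",
    "synth_expression",
]


@dataclass
class SimulationConfig:
    """Parameters of the particle simulation (reduced LJ units).

    The defaults reproduce the benchmark protocol: 6 types x 200 cells in a
    [-50, 50]^2 periodic box, sigma=2, rc=5, T=1, m=1, all eps=1 unless a
    scenario raises specific pairs.
    """

    n_types: int = 6
    cells_per_type: int = 200
    box: float = 100.0  # side length, box spans [-box/2, box/2]
    eps: Optional[np.ndarray] = None  # (n_types, n_types), defaults to ones
    sigma: float = 2.0
    rc: float = 5.0
    temperature: float = 1.0
    mass: float = 1.0
    dt: float = 0.005
    damping: float = 1.0  # damping time; friction gamma = 1/damping
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps is None:
            self.eps = np.ones((self.n_types, self.n_types))
        self.eps = np.asarray(self.eps, dtype=float)
        if self.eps.shape != (self.n_types, self.n_types):
            raise ValueError("eps must be (n_types, n_types)")
        if not np.allclose(self.eps, self.eps.T):
            raise ValueError("eps must be symmetric")
        if (self.eps <= 0).any():
            raise ValueError("eps must be positive")
        if self.rc <= self.sigma:
            raise ValueError("interaction cutoff rc must exceed sigma")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")

    @property
    def n_particles(self) -> int:
        return self.n_types * self.cells_per_type


@dataclass
class TissueSnapshot:
    """Final particle configuration with type labels and diagnostics."""

    coords: np.ndarray  # (n, 2), wrapped into the box
    type_labels: np.ndarray  # strings 'T0'..'T{n-1}'
    config: SimulationConfig
    final_temperature: float

    @property
    def type_index(self) -> np.ndarray:
        return np.array([int(str(t)[1:]) for t in self.type_labels])


def lj_potential(r, eps: float = 1.0, sigma: float = 2.0):
    """Lennard-Jones pair potential; V(sigma) = 0, V(2^(1/6) sigma) = -eps."""
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def scenario_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """The two benchmark affinity scenarios.

    ``scenario1`` raises eps(T0,T2)=3 and eps(T3,T5)=5 above the baseline of
    1; ``scenario2`` additionally raises eps(T2,T3)=10 and eps(T1,T3)=8,
    establishing a distinct affinity order around T3.
    """
    eps = np.ones((6, 6))
    if name == "scenario1":
        eps[0, 2] = eps[2, 0] = 3.0
        eps[3, 5] = eps[5, 3] = 5.0
    elif name == "scenario2":
        eps[0, 2] = eps[2, 0] = 3.0
        eps[3, 5] = eps[5, 3] = 5.0
        eps[2, 3] = eps[3, 2] = 10.0
        eps[1, 3] = eps[3, 1] = 8.0
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return SimulationConfig(eps=eps, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _init_positions(n, L, min_sep, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    pos = np.empty((n, 2))
    ms2 = min_sep * min_sep
    placed = 0
    tries = 0
    while placed < n:
        x = np.random.uniform(-L / 2, L / 2)
        y = np.random.uniform(-L / 2, L / 2)
        ok = True
        for j in range(placed):
            rx = x - pos[j, 0]
            ry = y - pos[j, 1]
            rx -= L * np.round(rx / L)
            ry -= L * np.round(ry / L)
            if rx * rx + ry * ry < ms2:
                ok = False
                break
        if ok:
            pos[placed, 0] = x
            pos[placed, 1] = y
            placed += 1
        tries += 1
        if tries > 2000 * n:
            return pos[:placed]
    return pos


@njit(cache=True, fastmath=True)
def _build_nlist(pos, rl, L, head, nxt, ncell, cw, nlist, nstart):  # pragma: no cover
    n = pos.shape[0]
    head[:] = -1
    for i in range(n):
        cx = int((pos[i, 0] + L / 2) / cw) % ncell
        cy = int((pos[i, 1] + L / 2) / cw) % ncell
        c = cx * ncell + cy
        nxt[i] = head[c]
        head[c] = i
    rl2 = rl * rl
    k = 0
    for i in range(n):
        nstart[i] = k
        cx = int((pos[i, 0] + L / 2) / cw) % ncell
        cy = int((pos[i, 1] + L / 2) / cw) % ncell
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                j = head[((cx + dx) % ncell) * ncell + (cy + dy) % ncell]
                while j >= 0:
                    if j > i:
                        rx = pos[i, 0] - pos[j, 0]
                        ry = pos[i, 1] - pos[j, 1]
                        rx -= L * np.round(rx / L)
                        ry -= L * np.round(ry / L)
                        if rx * rx + ry * ry < rl2:
                            nlist[k] = j
                            k += 1
                    j = nxt[j]
    nstart[n] = k
    return k


@njit(cache=True, fastmath=True)
def _forces(pos, types, eps, sigma, rc, L, nlist, nstart, forces):  # pragma: no cover
    n = pos.shape[0]
    forces[:] = 0.0
    rc2 = rc * rc
    pe = 0.0
    for i in range(n):
        for k in range(nstart[i], nstart[i + 1]):
            j = nlist[k]
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rx -= L * np.round(rx / L)
            ry -= L * np.round(ry / L)
            r2 = rx * rx + ry * ry
            if r2 < rc2:
                e = eps[types[i], types[j]]
                sr2 = sigma * sigma / r2
                sr6 = sr2 * sr2 * sr2
                pe += 4.0 * e * (sr6 * sr6 - sr6)
                fmag = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / r2
                forces[i, 0] += fmag * rx
                forces[i, 1] += fmag * ry
                forces[j, 0] -= fmag * rx
                forces[j, 1] -= fmag * ry
    return pe


@njit(cache=True, fastmath=True)
def _run_langevin(pos, types, eps, sigma, rc, L, dt, gamma, temp, mass,
                  n_steps, seed):  # pragma: no cover - numba
    """BAOAB Langevin dynamics; returns mean kinetic temperature over the
    second half of the trajectory (in 2D, T = <KE>/N with kB = 1)."""
    np.random.seed(seed)
    n = pos.shape[0]
    vel = np.random.normal(0.0, np.sqrt(temp / mass), (n, 2))
    skin = 0.5 * rc
    rl = rc + skin
    ncell = max(3, int(L // rl))
    cw = L / ncell
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    nlist = np.empty(n * 96, dtype=np.int64)
    nstart = np.empty(n + 1, dtype=np.int64)
    forces = np.zeros((n, 2))
    ref = pos.copy()
    _build_nlist(pos, rl, L, head, nxt, ncell, cw, nlist, nstart)
    _forces(pos, types, eps, sigma, rc, L, nlist, nstart, forces)
    ef = np.exp(-gamma * dt)
    osd = np.sqrt(temp / mass * (1.0 - ef * ef))
    half = 0.5 * dt / mass
    ke_acc = 0.0
    ke_n = 0
    for step in range(n_steps):
        maxd2 = 0.0
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            vel[i, 0] = ef * vel[i, 0] + osd * np.random.normal()
            vel[i, 1] = ef * vel[i, 1] + osd * np.random.normal()
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            if pos[i, 0] >= L / 2:
                pos[i, 0] -= L
            elif pos[i, 0] < -L / 2:
                pos[i, 0] += L
            if pos[i, 1] >= L / 2:
                pos[i, 1] -= L
            elif pos[i, 1] < -L / 2:
                pos[i, 1] += L
            ddx = pos[i, 0] - ref[i, 0]
            ddy = pos[i, 1] - ref[i, 1]
            ddx -= L * np.round(ddx / L)
            ddy -= L * np.round(ddy / L)
            d2 = ddx * ddx + ddy * ddy
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > (0.5 * skin) ** 2:
            ref[:] = pos
            _build_nlist(pos, rl, L, head, nxt, ncell, cw, nlist, nstart)
        _forces(pos, types, eps, sigma, rc, L, nlist, nstart, forces)
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
        if step >= n_steps // 2:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2)
            ke_acc += ke / n
            ke_n += 1
    return ke_acc / max(ke_n, 1)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def simulate_tissue(config: SimulationConfig) -> TissueSnapshot:
    """Run the Langevin LJ simulation and return the final configuration.

    Particles are placed uniformly at random with a minimum separation of
    sigma (rejection sampling); placement failure (density too high) raises.
    Type labels 'T0'..'T{n-1}' are assigned in contiguous blocks; motion is
    confined to the 2D periodic box. The returned ``final_temperature`` is
    the mean kinetic temperature over the second half of the run.
    """
    n = config.n_particles
    ss = np.random.SeedSequence(config.seed)
    seed_init, seed_md = [int(s) % (2 ** 31) for s in ss.generate_state(2)]
    pos = _init_positions(n, config.box, config.sigma, seed_init)
    if pos.shape[0] < n:
        raise ValueError(
            f"could only place {pos.shape[0]}/{n} particles at min separation "
            f"{config.sigma}; density too high"
        )
    types = np.repeat(np.arange(config.n_types), config.cells_per_type).astype(np.int64)
    gamma = 1.0 / config.damping
    temp = _run_langevin(
        pos, types, config.eps, config.sigma, config.rc, config.box,
        config.dt, gamma, config.temperature, config.mass,
        config.n_steps, seed_md,
    )
    labels = np.array([f"T{t}" for t in types], dtype=object)
    return TissueSnapshot(pos, labels, config, float(temp))


# ---------------------------------------------------------------------------
# synthetic expression
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpressionConfig:
    """Parameters of the negative-binomial expression generator.

    Each type owns a block of genes: the first ``markers_per_type`` are
    constitutive markers, the rest respond to the type's latent factor
    activity. A spatial cell's activity is its base draw plus ``gamma``
    times the mean base activity of neighbouring cells of the designated
    partner type (plus Gaussian noise), which plants a cross-type factor
    coupling of known strength.
    """

    n_genes: int = 60
    markers_per_type: int = 5
    genes_per_type: int = 10
    marker_rate: float = 5.0
    base_rate: float = 0.2
    loading: float = 1.0
    activity_mean: float = 1.0
    activity_sd: float = 0.3
    nb_dispersion: float = 10.0
    depth: float = 1000.0
    depth_sd_log: float = 0.2
    gamma: float = 0.0  # cross-type coupling coefficient
    coupling: Optional[Dict[int, int]] = None  # central type -> partner type
    noise_sd: float = 0.1
    neighbor_radius: float = 5.0
    ref_cells_per_type: int = 200
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth returned alongside the synthetic datasets."""

    labels_spatial: np.ndarray
    labels_reference: np.ndarray
    activity_spatial: np.ndarray
    activity_reference: np.ndarray
    gamma: float
    coupling: Dict[int, int]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/theta."""
    shape = theta
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def synth_expression(
    snapshot: TissueSnapshot,
    cfg: SyntheticExpressionConfig,
) -> tuple[SpatialDataset, ReferenceDataset, SimTruth]:
    """Synthesise spatial + reference expression over a tissue snapshot.

    Gene rates are exp(baseline + loading * activity), normalised per cell
    and scaled by a lognormal sequencing depth; counts are negative
    binomial. The reference is drawn from the same per-type programs with
    independent activities and no spatial coupling.
    """
    n_types = snapshot.config.n_types
    need = n_types * cfg.genes_per_type
    if cfg.n_genes < need:
        raise ValueError(f"n_genes={cfg.n_genes} < {need} needed for {n_types} types")
    if cfg.markers_per_type > cfg.genes_per_type:
        raise ValueError("markers_per_type cannot exceed genes_per_type")
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"g{i:03d}" for i in range(cfg.n_genes)], dtype=object)
    types = snapshot.type_index
    n_sp = len(types)
    coupling = dict(cfg.coupling or {})

    # per-type baseline (log) and factor loading vectors
    log_base = np.full((n_types, cfg.n_genes), np.log(cfg.base_rate))
    loadings = np.zeros((n_types, cfg.n_genes))
    for t in range(n_types):
        block = slice(t * cfg.genes_per_type, (t + 1) * cfg.genes_per_type)
        log_base[t, block] = np.log(cfg.marker_rate)
        resp = slice(t * cfg.genes_per_type + cfg.markers_per_type,
                     (t + 1) * cfg.genes_per_type)
        loadings[t, resp] = cfg.loading

    # base activities, then coupled spatial activities
    base_act = rng.normal(cfg.activity_mean, cfg.activity_sd, n_sp)
    act_sp = base_act.copy()
    if cfg.gamma != 0.0 and coupling:
        from scipy.spatial import cKDTree

        tree = cKDTree(snapshot.coords)
        nbr_lists = tree.query_ball_tree(tree, cfg.neighbor_radius)
        for c in range(n_sp):
            partner = coupling.get(types[c])
            if partner is None:
                continue
            nbrs = [j for j in nbr_lists[c] if j != c and types[j] == partner]
            if nbrs:
                act_sp[c] = (base_act[c]
                             + cfg.gamma * float(np.mean(base_act[nbrs]))
                             + rng.normal(0.0, cfg.noise_sd))
    act_sp = np.maximum(act_sp, 0.0)

    def draw_counts(type_vec, activities):
        n = len(type_vec)
        depth = np.exp(rng.normal(np.log(cfg.depth), cfg.depth_sd_log, n))
        rates = np.exp(log_base[type_vec] + loadings[type_vec] * activities[:, None])
        rates /= rates.sum(axis=1, keepdims=True)
        mean = rates * depth[:, None]
        return _nb_counts(rng, mean, cfg.nb_dispersion)

    sp_counts = draw_counts(types, act_sp)
    sp_ids = np.array([f"sp{i:05d}" for i in range(n_sp)], dtype=object)
    spatial = SpatialDataset(
        CountMatrix(sp_counts.astype(float), sp_ids, genes),
        snapshot.coords.copy(),
        None,
    )

    ref_types = np.repeat(np.arange(n_types), cfg.ref_cells_per_type)
    act_ref = np.maximum(
        rng.normal(cfg.activity_mean, cfg.activity_sd, len(ref_types)), 0.0
    )
    ref_counts = draw_counts(ref_types, act_ref)
    ref_ids = np.array([f"sc{i:05d}" for i in range(len(ref_types))], dtype=object)
    ref_labels = np.array([f"T{t}" for t in ref_types], dtype=object)
    reference = ReferenceDataset(
        CountMatrix(ref_counts.astype(float), ref_ids, genes), ref_labels
    )
    truth = SimTruth(
        snapshot.type_labels.copy(), ref_labels.copy(),
        act_sp, act_ref, cfg.gamma, coupling,
    )
    return spatial, reference, truth
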