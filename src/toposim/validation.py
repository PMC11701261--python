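"""Physics validation measurements: the quantitative self-checks of the model.

These are the standard polymer/extrusion observables used to verify the
engine: NVE energy drift, equipartition, phantom-chain persistence length,
extruder residence time and steady-state loop size, bridging-induced
protein enrichment, and heteromorphic (i, i+2) spacing.  They are shared
between the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from . import _kernels
from .dynamics import (
    N_TYPES,
    SystemState,
    eps_matrix,
    integrate,
    maxwell_velocities,
)
from .extrusion import ExtrusionParams, ExtruderSystem
from .forcefield import ForceFieldParams, lj_normalization


def _chain_state(n: int, rng: np.random.Generator, spacing: float = 0.97,
                 box_side: float = 1e6) -> SystemState:
    """A straight chain in a huge open box (no walls ever reached)."""
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    pos += box_side / 2
    return SystemState(
        pos=pos,
        vel=maxwell_velocities(n, rng),
        box=np.full(3, box_side),
        periodic=False,
        n_chain=n,
        types=np.zeros(n, dtype=np.int64),
        fene_bonds=np.stack([np.arange(n - 1), np.arange(1, n)],
                            axis=1).astype(np.int64),
    )


def _kp_chain_state(
    n: int, rng: np.random.Generator, lp: float, spacing: float = 0.97,
    box_side: float = 1e6,
) -> SystemState:
    """Chain drawn from the equilibrium discrete Kratky-Porod distribution
    (bond angles ~ exp(lp cos theta) sin theta), so no slow global tangent
    memory has to be relaxed away by dynamics."""
    u = rng.random(n - 2)
    cos_t = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * lp)) / lp
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
    phi = rng.random(n - 2) * 2.0 * np.pi
    dirs = np.empty((n - 1, 3))
    dirs[0] = (0.0, 0.0, 1.0)
    for k in range(1, n - 1):
        t = dirs[k - 1]
        # orthonormal frame around the previous tangent
        a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        dirs[k] = (cos_t[k - 1] * t
                   + sin_t[k - 1] * (np.cos(phi[k - 1]) * e1
                                     + np.sin(phi[k - 1]) * e2))
    pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(spacing * dirs, axis=0)])
    pos += box_side / 2
    return SystemState(
        pos=pos,
        vel=maxwell_velocities(n, rng),
        box=np.full(3, box_side),
        periodic=False,
        n_chain=n,
        types=np.zeros(n, dtype=np.int64),
        fene_bonds=np.stack([np.arange(n - 1), np.arange(1, n)],
                            axis=1).astype(np.int64),
    )


def bond_correlation_samples(pos: np.ndarray, s_max: int = 10) -> np.ndarray:
    """Mean cos(theta(s)) between bond vectors s bonds apart, s = 1..s_max."""
    bonds = np.diff(pos, axis=0)
    units = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    out = np.empty(s_max)
    for s in range(1, s_max + 1):
        out[s - 1] = (units[:-s] * units[s:]).sum(axis=1).mean()
    return out


def fit_persistence_length(mean_cos: np.ndarray) -> float:
    """Decay length (in bonds = sigma) from a weighted least-squares fit of
    ln<cos theta(s)> versus s.

    Weights are the delta-method variances of the log-transformed means
    (var[ln x] ~ var[x]/x^2, so w ~ x^2): the nearly noise-free short-range
    correlations anchor the slope instead of the slowly-converging tail.
    """
    keep = mean_cos > 0
    s = np.arange(1, len(mean_cos) + 1)[keep]
    x = mean_cos[keep]
    y = np.log(x)
    w = x ** 2
    X = np.stack([s.astype(float), np.ones_like(s, dtype=float)], axis=1)
    W = np.diag(w)
    slope = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)[0]
    return -1.0 / slope


def phantom_chain_persistence(
    n_beads: int = 500,
    equil_steps: int = 200_000,
    prod_steps: int = 1_000_000,
    sample_every: int = 1_000,
    seed: int = 1,
    lp: float = 4.0,
    s_max: int = 10,
) -> tuple[float, np.ndarray]:
    """Persistence length of a phantom chain (FENE + bending only).

    Nonbonded excluded volume is off; the FENE bond keeps its WCA core so
    the bond length stays ~0.97 sigma.  Returns (fitted decay length in
    sigma, the mean cos(theta(s)) profile).
    """
    rng = np.random.default_rng(seed)
    ff = replace(ForceFieldParams(), bend_lp=lp)
    state = _kp_chain_state(n_beads, rng, lp)
    integrate(state, equil_steps, True, rng, ff, nonbonded=False, wall_k=0.0)
    acc = np.zeros(s_max)
    n_samples = 0
    done = 0
    while done < prod_steps:
        chunk = min(sample_every, prod_steps - done)
        integrate(state, chunk, True, rng, ff, nonbonded=False, wall_k=0.0)
        acc += bond_correlation_samples(state.pos, s_max)
        n_samples += 1
        done += chunk
    mean_cos = acc / n_samples
    return fit_persistence_length(mean_cos), mean_cos


def nve_energy_drift(n_steps: int = 10_000, seed: int = 1) -> float:
    """Relative drift of the total energy of an isolated FENE dimer in NVE
    mode (thermostat off): |mean(E last 10%) - mean(E first 10%)| / |E|."""
    rng = np.random.default_rng(seed)
    state = _chain_state(2, rng, spacing=1.1)
    state.vel = maxwell_velocities(2, rng)
    ff = ForceFieldParams()
    energies = []
    empty_pairs = np.empty((0, 2), dtype=np.int64)
    harm_b, harm_k, harm_r0 = state.harm_arrays(ff)
    # sample every step: the symplectic integrator's bounded energy
    # oscillation averages out, leaving only secular drift
    for _ in range(n_steps):
        integrate(state, 1, thermostat=False, ff=ff,
                  nonbonded=False, wall_k=0.0)
        pe = _kernels.compute_potential(
            state.pos, state.box, state.periodic,
            state.fene_bonds, ff.fene_k, ff.fene_r0,
            harm_b, harm_k, harm_r0,
            state.n_chain, ff.bend_lp,
            empty_pairs, state.types, np.zeros((N_TYPES, N_TYPES)),
            lj_normalization(ff.tf_cutoff), ff.tf_cutoff, 0.0, 0.0,
        )
        ke = 0.5 * (state.vel ** 2).sum()
        energies.append(pe + ke)
    energies = np.array(energies)
    tenth = max(1, len(energies) // 10)
    drift = abs(energies[-tenth:].mean() - energies[:tenth].mean())
    return float(drift / abs(energies[:tenth].mean()))


def equipartition_ke_per_bead(
    n_beads: int = 1_000, n_samples: int = 200, steps_between: int = 100,
    seed: int = 1,
) -> float:
    """Mean kinetic energy per bead of a thermostatted ideal gas (no forces);
    should equal (3/2) kBT."""
    rng = np.random.default_rng(seed)
    state = _chain_state(n_beads, rng, spacing=5.0)
    state.fene_bonds = np.empty((0, 2), dtype=np.int64)
    state.n_chain = 0  # no angles either
    ke = []
    integrate(state, 500, True, rng, nonbonded=False, wall_k=0.0, kappa=0.0)
    for _ in range(n_samples):
        integrate(state, steps_between, True, rng, nonbonded=False,
                  wall_k=0.0, kappa=0.0)
        ke.append(0.5 * (state.vel ** 2).sum() / n_beads)
    return float(np.mean(ke))


def extruder_kinetics(
    n_beads: int = 40_000,
    n_extruders: int = 20,
    dt_sweep: float = 100.0,
    min_events: int = 500,
    warmup_sweeps: int = 1_000,
    seed: int = 1,
    params: Optional[ExtrusionParams] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-free extrusion kinetics on a long chain at low density.

    Returns (lifetimes in tau of completed residences, loop-size samples in
    beads taken every sweep after warmup).  Low density keeps extruder
    collisions rare so the loop-size scale reflects processivity alone.
    """
    params = params or ExtrusionParams(density=1000.0 * n_extruders / n_beads)
    rng = np.random.default_rng(seed)
    system = ExtruderSystem(n_beads, params)
    system.seed(n_extruders, rng)
    loop_samples = []
    for _ in range(warmup_sweeps):
        system.sweep(dt_sweep, rng)
    system.unbind_log.clear()
    while len(system.unbind_log) < min_events:
        system.sweep(dt_sweep, rng)
        loop_samples.append(system.loop_sizes().mean())
    lifetimes = np.array([lt for lt, _ in system.unbind_log])
    return lifetimes, np.array(loop_samples)


def _bridging_state(
    n_chain: int, n_tf: int, marked: bool, rng: np.random.Generator,
    block: slice,
) -> SystemState:
    """Small periodic system: a chain (optionally with an accessible block)
    plus active proteins, used for the bridging-attraction check."""
    from .dynamics import box_from_density, init_rosette, _place_tfs

    L = box_from_density(n_chain)
    pos, height = init_rosette(n_chain, L)
    state = SystemState(
        pos=pos,
        vel=maxwell_velocities(n_chain, rng),
        box=np.array([L, L, max(height, L)]),
        periodic=False,
        n_chain=n_chain,
        types=np.zeros(n_chain, dtype=np.int64),
        fene_bonds=np.stack([np.arange(n_chain - 1), np.arange(1, n_chain)],
                            axis=1).astype(np.int64),
        soft_backbone=True,
    )
    if marked:
        state.types[block] = 1  # accessible (ATAC) beads
    ff = ForceFieldParams()
    integrate(state, 2_000, True, rng, ff, soft_ramp=(0.0, 500.0))
    state.soft_backbone = False
    scale = L / state.box[2]
    state.pos[:, 2] *= scale
    state.box = np.array([L, L, L])
    integrate(state, 2_000, True, rng, ff)
    state.periodic = True
    integrate(state, 1_000, True, rng, ff, soft_ramp=(50.0, 500.0))
    integrate(state, 2_000, True, rng, ff)
    tf_pos = _place_tfs(state, n_tf, rng)
    state.pos = np.vstack([state.pos, tf_pos])
    state.vel = np.vstack([state.vel, maxwell_velocities(n_tf, rng)])
    state.types = np.concatenate([state.types,
                                  np.full(n_tf, 16, dtype=np.int64)])
    state.tf_species = np.zeros(n_tf, dtype=np.int64)
    state.tf_bound = np.ones(n_tf, dtype=bool)
    return state


def bridging_enrichment(
    seed: int,
    marked: bool,
    n_chain: int = 60,
    n_tf: int = 20,
    block: slice = slice(20, 40),
    equil_steps: int = 15_000,
    prod_steps: int = 30_000,
    sample_every: int = 1_000,
    near: float = 2.0,
) -> float:
    """Mean number of proteins within `near` sigma of the (would-be) block.

    With `marked` the block carries the accessible mark and active proteins
    bind it at 7 kBT; without, the chain is mark-free and proteins are
    identical but have nothing to bind.  The contrast between the two is
    the bridging-induced attraction signal.
    """
    rng = np.random.default_rng(seed)
    state = _bridging_state(n_chain, n_tf, marked, rng, block)
    ff = ForceFieldParams()
    eps = eps_matrix()
    integrate(state, equil_steps, True, rng, ff, eps)
    counts = []
    for _ in range(prod_steps // sample_every):
        integrate(state, sample_every, True, rng, ff, eps)
        block_pos = state.pos[block]
        tf_pos = state.pos[n_chain:]
        d = tf_pos[:, None, :] - block_pos[None, :, :]
        d -= state.box * np.rint(d / state.box)
        dist = np.sqrt((d ** 2).sum(axis=2)).min(axis=1)
        counts.append((dist < near).sum())
    return float(np.mean(counts))
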