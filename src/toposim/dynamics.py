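"""Langevin dynamics of the chromatin + protein system and the staged protocol.

The equations of motion are the underdamped Langevin equations (unit mass,
friction gamma = 2, kBT = 1), integrated with a Langevin-middle (BAOAB)
discretization at dt = 0.01 tau; with the thermostat off the integrator is
plain velocity-Verlet and conserves energy (validation mode).

The staged protocol mirrors a production pipeline for one genome fragment:
a mitotic-like stack-of-rosettes initial conformation is relaxed under a
soft push-off potential, the box is compressed to a cube whose side gives a
chromatin density of ~6.5 Mbp/um^3, the fiber is relaxed (fixed then
periodic boundaries), memory of the rosette is erased by boundary-free loop
extrusion, heteromorphic crumple springs and then protein beads are added,
and finally production runs sample conformations while chromatin-chromatin
and protein-chromatin attractions switch on in sequence.  A single
desk-scale factor shrinks every stage duration proportionally for
laptop-sized experiments.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .annotation import BeadTrack, sample_ctcf_activation
from .extrusion import ExtruderSystem, ExtrusionParams, extruder_count
from .forcefield import (
    AffinityTable,
    ForceFieldParams,
    MARKS,
    SPECIES,
    SimulationUnits,
    lj_normalization,
    pair_affinity,
)

# bead type codes: 0..15 chromatin mark bitmask; 16+s protein species s in
# binding state; 19+s protein species s in non-binding (steric) state
N_CHROMATIN_TYPES = 16
N_TYPES = 22
GAMMA_DEFAULT = 2.0


def box_from_density(
    kbp: float, density_mbp_um3: float = 6.5, physical_sigma_nm: float = 25.0
) -> float:
    """Cubic box side (in sigma) giving the target chromatin density.

    L = (kbp / (density x sigma_um^3 x 10^3))^(1/3) with sigma = 1 kbp of
    chromatin.  The default 6.5 Mbp/um^3 is the nuclear estimate for a
    human diploid cell (~6.5 Gbp in a ~10 um nucleus).
    """
    if kbp <= 0 or density_mbp_um3 <= 0 or physical_sigma_nm <= 0:
        raise ValueError("all inputs must be positive")
    sigma_um = physical_sigma_nm * 1e-3
    return (kbp / (density_mbp_um3 * sigma_um ** 3 * 1e3)) ** (1.0 / 3.0)


def density_from_box(
    kbp: float, box_side_sigma: float, physical_sigma_nm: float = 25.0
) -> float:
    """Inverse of :func:`box_from_density`: Mbp/um^3 implied by a box side."""
    sigma_um = physical_sigma_nm * 1e-3
    return (kbp * 1e-3) / (box_side_sigma * sigma_um) ** 3


@dataclass
class TFPopulation:
    """Multivalent protein counts: total 10% of chromatin beads, split
    active : polycomb : HP1 = 1/4 : 1/8 : 5/8 (floor per species, remainder
    to HP1, the largest share); binding<->non-binding switching at ksw."""

    n_active: int
    n_polycomb: int
    n_hp1: int
    ksw: float = 1e-3

    @classmethod
    def from_chain(cls, n_beads: int, fraction: float = 0.10, ksw: float = 1e-3):
        total = int(round(fraction * n_beads))
        n_active = total // 4
        n_polycomb = total // 8
        return cls(n_active, n_polycomb, total - n_active - n_polycomb, ksw)

    @property
    def total(self) -> int:
        return self.n_active + self.n_polycomb + self.n_hp1

    def species_array(self) -> np.ndarray:
        return np.repeat(
            np.arange(3), [self.n_active, self.n_polycomb, self.n_hp1]
        ).astype(np.int64)


def eps_matrix(
    affinities: Optional[AffinityTable] = None,
    self_eps: float = 0.4,
    chromatin_attraction: bool = True,
    tf_attraction: bool = True,
) -> np.ndarray:
    """Pair well-depth lookup over bead type codes.

    Chromatin-chromatin pairs where neither bead carries H3K27ac (bit 1) get
    the weak self attraction; binding proteins see the maximum affinity among
    a bead's marks; non-binding proteins and protein-protein pairs are
    purely steric (0 -> WCA in the kernels).
    """
    if affinities is None:
        affinities = AffinityTable()
    E = np.zeros((N_TYPES, N_TYPES))
    if chromatin_attraction:
        for a in range(N_CHROMATIN_TYPES):
            if a >> 1 & 1:
                continue
            for b in range(N_CHROMATIN_TYPES):
                if not (b >> 1 & 1):
                    E[a, b] = self_eps
    if tf_attraction:
        for s, species in enumerate(SPECIES):
            t_on = N_CHROMATIN_TYPES + s
            for a in range(N_CHROMATIN_TYPES):
                marks = {MARKS[bit] for bit in range(4) if a >> bit & 1}
                eps = pair_affinity(species, True, marks, affinities)
                E[t_on, a] = E[a, t_on] = eps
    return E


@dataclass
class SystemState:
    """Positions/velocities of chromatin + protein beads plus topology.

    Positions are kept unwrapped; periodic images are resolved by minimum
    image inside the kernels, so backbone unwrapping for center-of-mass
    observables is trivial.
    """

    pos: np.ndarray
    vel: np.ndarray
    box: np.ndarray           # (3,) cuboid dimensions in sigma
    periodic: bool
    n_chain: int
    types: np.ndarray         # (N,) bead type codes
    fene_bonds: np.ndarray
    crumple_bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    extruder_bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    soft_backbone: bool = False   # harmonic backbone during the push-off stage
    tf_species: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tf_bound: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    clock: float = 0.0

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "SystemState":
        return copy.deepcopy(self)

    def harm_arrays(self, ff: ForceFieldParams, backbone_k=100.0, backbone_r0=1.1):
        """Assemble the harmonic-bond arrays for the kernels."""
        bonds, ks, r0s = [], [], []
        if self.soft_backbone:
            bonds.append(self.fene_bonds)
            ks.append(np.full(len(self.fene_bonds), backbone_k))
            r0s.append(np.full(len(self.fene_bonds), backbone_r0))
        if len(self.crumple_bonds):
            bonds.append(self.crumple_bonds)
            ks.append(np.full(len(self.crumple_bonds), ff.crumple_k))
            r0s.append(np.full(len(self.crumple_bonds), ff.crumple_r0))
        if len(self.extruder_bonds):
            bonds.append(self.extruder_bonds)
            ks.append(np.full(len(self.extruder_bonds), ff.extruder_k))
            r0s.append(np.full(len(self.extruder_bonds), ff.extruder_r0))
        if not bonds:
            return (np.empty((0, 2), dtype=np.int64), np.empty(0), np.empty(0))
        return (
            np.concatenate(bonds).astype(np.int64),
            np.concatenate(ks),
            np.concatenate(r0s),
        )

    def update_tf_types(self) -> None:
        n_tf = len(self.tf_species)
        if n_tf == 0:
            return
        codes = N_CHROMATIN_TYPES + self.tf_species + np.where(self.tf_bound, 0, 3)
        self.types[self.n_chain:self.n_chain + n_tf] = codes


def maxwell_velocities(n: int, rng: np.random.Generator, kT: float = 1.0) -> np.ndarray:
    return rng.standard_normal((n, 3)) * math.sqrt(kT)


def init_rosette(
    n_beads: int,
    xy_side: float,
    spacing: float = 1.1,
    base_radius: float = 2.4,
    lobe_amplitude: float = 1.0,
    lobes_per_turn: int = 3,
    rise_rate: float = 0.25,
    margin: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Mitotic-like stack-of-rosettes curve, resampled to ~`spacing` per bead.

    The curve is a helix whose radius is modulated into lobes ("petals"),
    rho(theta) = R0 + dR cos(m theta), z = c theta, chosen smooth enough
    that arclength resampling at 1.1 sigma yields consecutive-bead chords
    within [0.9, 1.3] sigma.  Exact petal geometry is cosmetic: the memory
    of this conformation is erased later by boundary-free extrusion.
    Returns (positions, box height).
    """
    if n_beads < 10:
        raise ValueError("need at least 10 beads")
    if 2 * (base_radius + lobe_amplitude) >= xy_side:
        raise ValueError("box xy side too small for the rosette radius")
    need = spacing * (n_beads + 2)
    theta_max = need / math.sqrt(base_radius ** 2 + rise_rate ** 2) * 1.5 + 20.0
    theta = np.linspace(0.0, theta_max, int(2000 * theta_max))
    rho = base_radius + lobe_amplitude * np.cos(lobes_per_turn * theta)
    pts = np.stack(
        [rho * np.cos(theta), rho * np.sin(theta), rise_rate * theta], axis=1
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < need:
        raise ValueError("rosette curve too short; increase rise or radius")
    targets = spacing * np.arange(n_beads)
    pos = np.empty((n_beads, 3))
    for a in range(3):
        pos[:, a] = np.interp(targets, cum, pts[:, a])
    # center on the box axis
    pos[:, 0] += xy_side / 2 - pos[:, 0].mean()
    pos[:, 1] += xy_side / 2 - pos[:, 1].mean()
    pos[:, 2] += margin - pos[:, 2].min()
    height = pos[:, 2].max() + margin
    return pos, height


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2 ** 31 - 1))


def integrate(
    state: SystemState,
    n_steps: int,
    thermostat: bool = True,
    rng: np.random.Generator | int | None = None,
    ff: Optional[ForceFieldParams] = None,
    eps: Optional[np.ndarray] = None,
    units: Optional[SimulationUnits] = None,
    soft_ramp: tuple[float, float] = (0.0, 0.0),
    wall_k: float = 100.0,
    nonbonded: bool = True,
    gamma: float = GAMMA_DEFAULT,
    kappa: Optional[float] = None,
    backbone_k: float = 100.0,
    backbone_r0: float = 1.1,
) -> SystemState:
    """Advance the system n_steps in place; deterministic under a fixed seed.

    A FENE overstretch (bond blow-up) raises RuntimeError with the step and
    bond — the fatal diagnostic demanded of the integrator.
    """
    ff = ff or ForceFieldParams()
    units = units or SimulationUnits()
    if eps is None:
        eps = np.zeros((N_TYPES, N_TYPES))
    if thermostat:
        if rng is None:
            raise ValueError("thermostat requires a seed or Generator")
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
    harm_bonds, harm_k, harm_r0 = state.harm_arrays(ff, backbone_k, backbone_r0)
    fene = (np.empty((0, 2), dtype=np.int64)
            if state.soft_backbone else state.fene_bonds)
    kp = ff.bend_lp if kappa is None else kappa
    n = state.n_beads
    # bound the pre-generated noise block to ~32 MB
    max_sub = max(1, int(1.4e6 / max(1, n)))
    dummy = np.zeros((1, 1, 3))
    done = 0
    while done < n_steps:
        sub = min(max_sub, n_steps - done)
        if thermostat:
            noise = rng.standard_normal((sub, n, 3))
        else:
            noise = dummy
        if n_steps > 1:
            a0 = soft_ramp[0] + (soft_ramp[1] - soft_ramp[0]) * done / (n_steps - 1)
            a1 = soft_ramp[0] + (soft_ramp[1] - soft_ramp[0]) * \
                min(n_steps - 1, done + sub - 1) / (n_steps - 1)
        else:
            a0, a1 = soft_ramp
        step, bad = _kernels.run_chunk(
            state.pos, state.vel, sub, units.timestep,
            gamma if thermostat else 0.0, 1.0,
            state.box, state.periodic,
            fene, ff.fene_k, ff.fene_r0,
            harm_bonds, harm_k, harm_r0,
            state.n_chain, kp,
            state.types, eps, lj_normalization(ff.tf_cutoff), ff.tf_cutoff,
            a0, a1,
            wall_k, nonbonded, 0.4,
            noise,
        )
        if step != -1:
            i, j = fene[bad] if len(fene) else (-1, -1)
            raise RuntimeError(
                f"FENE bond blow-up at step {done + step} "
                f"(clock {state.clock:.1f} tau), bond {bad} ({i}-{j}); "
                "reduce the timestep"
            )
        done += sub
    state.clock += n_steps * units.timestep
    return state


def switch_tf_states(
    state: SystemState, dt: float, ksw: float, rng: np.random.Generator
) -> SystemState:
    """Flip each protein between binding and non-binding with prob ksw*dt."""
    n_tf = len(state.tf_species)
    if n_tf == 0 or ksw == 0.0:
        return state
    flips = rng.random(n_tf) < ksw * dt
    state.tf_bound ^= flips
    state.update_tf_types()
    return state


@dataclass
class ProtocolSchedule:
    """Stage durations in tau (full scale); `scaled` shrinks everything."""

    rosette_relax: float = 600.0
    soft_max: float = 500.0
    backbone_k: float = 100.0
    backbone_r0: float = 1.1
    compress: float = 1.0e4
    fixed_relax: float = 5.0e3
    periodic_relax: float = 2.5e4
    ctcf_free_extrusion: float = 2.0e4
    relax_density: float = 7.5
    crumple_relax: float = 1.0e4
    tf_equil: float = 1.0e3
    production: float = 3.0e5
    cc_on_at: float = 1.0e4
    tf_on_at: float = 5.0e4
    sample_every: float = 2.0e3
    sample_window: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("rosette_relax", "compress", "fixed_relax", "periodic_relax",
                     "ctcf_free_extrusion", "crumple_relax", "tf_equil",
                     "production", "sample_every", "sample_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "ProtocolSchedule":
        if factor <= 0:
            raise ValueError("desk-scale factor must be positive")
        durations = dict(
            rosette_relax=self.rosette_relax, compress=self.compress,
            fixed_relax=self.fixed_relax, periodic_relax=self.periodic_relax,
            ctcf_free_extrusion=self.ctcf_free_extrusion,
            crumple_relax=self.crumple_relax, tf_equil=self.tf_equil,
            production=self.production, cc_on_at=self.cc_on_at,
            tf_on_at=self.tf_on_at, sample_every=self.sample_every,
            sample_window=self.sample_window,
        )
        return replace(self, **{k: v * factor for k, v in durations.items()})


@dataclass
class Trajectory:
    """Sampled conformations of one production run."""

    frames: np.ndarray        # (F, N, 3) unwrapped positions
    times: np.ndarray         # (F,) clock in tau
    box: np.ndarray
    n_chain: int
    metadata: dict = field(default_factory=dict)

    def chromatin(self) -> np.ndarray:
        return self.frames[:, : self.n_chain]

    def save(self, path) -> None:
        np.savez_compressed(
            path, frames=self.frames, times=self.times, box=self.box,
            n_chain=self.n_chain, metadata=np.bytes_(repr(self.metadata).encode()),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        import ast

        z = np.load(path)
        return cls(
            frames=z["frames"], times=z["times"], box=z["box"],
            n_chain=int(z["n_chain"]),
            metadata=ast.literal_eval(z["metadata"].tobytes().decode()),
        )


def crumple_bond_list(n_chain: int, ac_flags: Optional[np.ndarray] = None) -> np.ndarray:
    """(i, i+2) compaction bonds; a bond is dropped when any of beads
    i, i+1, i+2 carries the H3K27ac mark (acetylated regions stay open)."""
    pairs = []
    for i in range(n_chain - 2):
        if ac_flags is not None and (ac_flags[i] or ac_flags[i + 1] or ac_flags[i + 2]):
            continue
        pairs.append((i, i + 2))
    return (np.array(pairs, dtype=np.int64)
            if pairs else np.empty((0, 2), dtype=np.int64))


def _place_tfs(
    state: SystemState, n_tf: int, rng: np.random.Generator, min_dist: float = 0.9
) -> np.ndarray:
    """Uniform random protein positions, rejection-sampled off existing beads."""
    L = state.box
    placed = []
    existing = state.pos
    for _ in range(n_tf):
        for _attempt in range(20000):
            cand = rng.random(3) * L
            d = existing - cand
            d -= L * np.rint(d / L)
            if (d ** 2).sum(axis=1).min() > min_dist ** 2:
                placed.append(cand)
                existing = np.vstack([existing, cand])
                break
        else:
            raise RuntimeError("could not place protein beads: box too dense")
    return np.array(placed)


def run_relaxation(
    track: BeadTrack,
    seed: int,
    desk_scale: float = 1.0,
    ff: Optional[ForceFieldParams] = None,
    schedule: Optional[ProtocolSchedule] = None,
    extr: Optional[ExtrusionParams] = None,
    tf_pop: Optional[TFPopulation] = None,
    units: Optional[SimulationUnits] = None,
    density_mbp_um3: float = 6.5,
    physical_sigma_nm: float = 25.0,
) -> SystemState:
    """Stages 1-7: rosette push-off, compression, relaxation, boundary-free
    extrusion, crumpling, protein equilibration.  Returns the relaxed state
    (crumple springs still genome-wide; production removes acetylated ones)."""
    ff = ff or ForceFieldParams()
    units = units or SimulationUnits(physical_sigma_nm=physical_sigma_nm)
    sched = (schedule or ProtocolSchedule()).scaled(desk_scale)
    extr = extr or ExtrusionParams()
    rng = np.random.default_rng(seed)
    dt = units.timestep

    n = track.fragment.n_beads
    L = box_from_density(n, density_mbp_um3, physical_sigma_nm)
    pos, height = init_rosette(n, L)
    state = SystemState(
        pos=pos,
        vel=maxwell_velocities(n, rng),
        box=np.array([L, L, max(height, L)]),
        periodic=False,
        n_chain=n,
        types=track.type_codes(),
        fene_bonds=np.stack(
            [np.arange(n - 1), np.arange(1, n)], axis=1).astype(np.int64),
        soft_backbone=True,
    )
    steps = lambda tau: max(1, int(round(tau / dt)))
    zero_eps = np.zeros((N_TYPES, N_TYPES))

    # 1. rosette relax under the ramped soft push-off, harmonic backbone
    integrate(state, steps(sched.rosette_relax), True, rng, ff, zero_eps, units,
              soft_ramp=(0.0, sched.soft_max),
              backbone_k=sched.backbone_k, backbone_r0=sched.backbone_r0)
    state.soft_backbone = False  # FENE + WCA from here on

    # 2. slow z compression to the target cube (affine remap per slab)
    n_slabs = 50
    z_target = L
    per_slab = steps(sched.compress) // n_slabs or 1
    for s in range(n_slabs):
        z_new = state.box[2] + (z_target - state.box[2]) / (n_slabs - s)
        scale_z = z_new / state.box[2]
        state.pos[:, 2] *= scale_z
        state.box = np.array([L, L, z_new])
        integrate(state, per_slab, True, rng, ff, zero_eps, units)
    state.box = np.array([L, L, L])

    # 3. relax with fixed boundaries, then 4. with periodic boundaries.
    # Opposite wall faces become adjacent at the switch, so the first slice
    # of the periodic stage re-ramps the soft push-off to dissolve the
    # cross-boundary overlaps before restoring full excluded volume.
    integrate(state, steps(sched.fixed_relax), True, rng, ff, zero_eps, units)
    state.periodic = True
    n_bridge = max(1, steps(sched.periodic_relax) // 10)
    integrate(state, n_bridge, True, rng, ff, zero_eps, units,
              soft_ramp=(50.0, sched.soft_max))
    integrate(state, steps(sched.periodic_relax) - n_bridge, True, rng, ff,
              zero_eps, units)

    # 5. boundary-free loop extrusion erases the rosette memory
    relax_extr = replace(extr, density=sched.relax_density)
    system = ExtruderSystem(n, relax_extr)
    system.seed(extruder_count(n, relax_extr.density), rng)
    _run_with_events(state, track, system, None, steps(sched.ctcf_free_extrusion),
                     rng, ff, zero_eps, units, extr.event_interval)

    # 6. crumple springs genome-wide, stiffness ramped up over the stage so
    # the simultaneous switch-on does not dump k_h (r-r0)^2 per bond at once
    state.crumple_bonds = crumple_bond_list(n)
    n_ramp = 10
    ramp_steps = steps(sched.crumple_relax) // n_ramp or 1
    for j in range(n_ramp):
        frac = (j + 1) / n_ramp
        ff_ramp = replace(ff, crumple_k=ff.crumple_k * frac ** 2)
        _run_with_events(state, track, system, None, ramp_steps,
                         rng, ff_ramp, zero_eps, units, extr.event_interval)

    pop = tf_pop or TFPopulation.from_chain(n)
    if pop.total:
        tf_pos = _place_tfs(state, pop.total, rng)
        state.pos = np.vstack([state.pos, tf_pos])
        state.vel = np.vstack([state.vel, maxwell_velocities(pop.total, rng)])
        state.types = np.concatenate([state.types, np.zeros(pop.total, dtype=np.int64)])
        state.tf_species = pop.species_array()
        state.tf_bound = rng.random(pop.total) < 0.5
        state.update_tf_types()
    state.extruder_bonds = system.bonds()
    _run_with_events(state, track, system, None, steps(sched.tf_equil),
                     rng, ff, zero_eps, units, extr.event_interval, ksw=pop.ksw)
    return state


def _run_with_events(
    state, track, extruders, boundaries, n_steps, rng, ff, eps, units,
    event_interval, ksw: float = 0.0,
):
    """Interleave MD chunks with extrusion sweeps and protein switching."""
    dt = units.timestep
    done = 0
    while done < n_steps:
        chunk = min(event_interval, n_steps - done)
        state.extruder_bonds = extruders.bonds() if extruders is not None else \
            np.empty((0, 2), dtype=np.int64)
        integrate(state, chunk, True, rng, ff, eps, units)
        sweep_dt = chunk * dt
        if extruders is not None:
            extruders.sweep(sweep_dt, rng)
        if ksw > 0.0:
            switch_tf_states(state, sweep_dt, ksw, rng)
        done += chunk


def run_production(
    relaxed: SystemState,
    track: BeadTrack,
    seed: int,
    desk_scale: float = 1.0,
    ff: Optional[ForceFieldParams] = None,
    schedule: Optional[ProtocolSchedule] = None,
    extr: Optional[ExtrusionParams] = None,
    affinities: Optional[AffinityTable] = None,
    units: Optional[SimulationUnits] = None,
    ksw: float = 1e-3,
) -> Trajectory:
    """One production run from a relaxed state.

    Acetylated crumple springs are removed, CTCF boundaries are drawn for
    this run, extruders are re-seeded at production density, and
    chromatin-chromatin then protein-chromatin attractions switch on at
    their scheduled times; conformations are sampled on the final window.
    """
    ff = ff or ForceFieldParams()
    units = units or SimulationUnits()
    sched = (schedule or ProtocolSchedule()).scaled(desk_scale)
    extr = extr or ExtrusionParams()
    affinities = affinities or AffinityTable()
    rng = np.random.default_rng(seed)
    dt = units.timestep

    state = relaxed.copy()
    n = state.n_chain
    state.crumple_bonds = crumple_bond_list(n, track.mark_flags("h3k27ac"))

    boundaries = sample_ctcf_activation(track, rng)
    system = ExtruderSystem(n, extr, boundaries)
    system.seed(extruder_count(n, extr.density), rng)

    eps_off = np.zeros((N_TYPES, N_TYPES))
    eps_cc = eps_matrix(affinities, ff.chromatin_self_eps, True, False)
    eps_full = eps_matrix(affinities, ff.chromatin_self_eps, True, True)

    total_steps = max(1, int(round(sched.production / dt)))
    cc_step = int(round(sched.cc_on_at / dt))
    tf_step = int(round(sched.tf_on_at / dt))
    t_start = state.clock
    sample_start = sched.production - sched.sample_window
    sample_times = np.arange(sample_start, sched.production + 1e-9, sched.sample_every)
    sample_times = sample_times[sample_times > 0]

    frames, times = [], []
    done = 0
    next_sample = 0
    while done < total_steps:
        if done < cc_step:
            eps, stop = eps_off, min(cc_step, total_steps)
        elif done < tf_step:
            eps, stop = eps_cc, min(tf_step, total_steps)
        else:
            eps, stop = eps_full, total_steps
        while done < stop:
            chunk = min(extr.event_interval, stop - done)
            if next_sample < len(sample_times):
                steps_to_sample = int(round(sample_times[next_sample] / dt)) - done
                if 0 < steps_to_sample < chunk:
                    chunk = steps_to_sample
            state.extruder_bonds = system.bonds()
            integrate(state, chunk, True, rng, ff, eps, units)
            sweep_dt = chunk * dt
            system.sweep(sweep_dt, rng)
            switch_tf_states(state, sweep_dt, ksw, rng)
            done += chunk
            while (next_sample < len(sample_times)
                   and done >= int(round(sample_times[next_sample] / dt))):
                frames.append(state.pos.copy())
                times.append(state.clock)
                next_sample += 1

    return Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        box=state.box.copy(),
        n_chain=n,
        metadata={
            "seed": seed,
            "desk_scale": desk_scale,
            "boundaries": boundaries,
            "clock_start": t_start,
            "n_extruders": len(system.left),
            "time_mapping": {
                "tau_brownian_tau": 2.0,
                "brownian_time_ms": 8.0,
            },
        },
    )


def run_protocol(
    track: BeadTrack,
    seed: int,
    n_relax: int = 1,
    n_production: int = 1,
    desk_scale: float = 1.0,
    **kwargs,
) -> list[Trajectory]:
    """Two-tier scheme: n_relax relaxed states x n_production seeds each."""
    rng = np.random.default_rng(seed)
    trajectories = []
    for _ in range(n_relax):
        relaxed = run_relaxation(track, _derive_seed(rng), desk_scale, **kwargs)
        for _ in range(n_production):
            trajectories.append(
                run_production(relaxed, track, _derive_seed(rng), desk_scale, **kwargs)
            )
    return trajectories


def ensemble_from_trajectories(trajectories: list[Trajectory]) -> np.ndarray:
    """Pooled chromatin conformations, shape (F_total, n_chain, 3)."""
    if not trajectories:
        raise ValueError("empty trajectory list")
    return np.concatenate([t.chromatin() for t in trajectories], axis=0)
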