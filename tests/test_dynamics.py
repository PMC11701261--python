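"""Integrator, box sizing, rosette initialization, protocol machinery."""

import numpy as np
import pytest

from toposim.dynamics import (
    ProtocolSchedule,
    SystemState,
    TFPopulation,
    Trajectory,
    box_from_density,
    crumple_bond_list,
    density_from_box,
    eps_matrix,
    init_rosette,
    integrate,
    maxwell_velocities,
    switch_tf_states,
)


# -- box sizing -------------------------------------------------------------


def test_box_density_round_trip():
    for kbp in (150, 2000, 50_000):
        L = box_from_density(kbp, 6.5, 25.0)
        assert density_from_box(kbp, L, 25.0) == pytest.approx(6.5, rel=1e-9)


def test_box_reference_value():
    assert box_from_density(2000, 6.5, 25.0) == pytest.approx(27.0, abs=0.05)


def test_box_scaling_law():
    L1 = box_from_density(1000)
    L2 = box_from_density(2000)
    assert L2 / L1 == pytest.approx(2 ** (1 / 3), rel=1e-12)


# -- rosette ----------------------------------------------------------------


@pytest.mark.parametrize("n", [10, 150, 1200])
def test_rosette_bead_spacing_within_band(n):
    pos, height = init_rosette(n, 12.0)
    chords = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    assert chords.min() >= 0.9
    assert chords.max() <= 1.3
    assert height > 0


def test_rosette_center_of_mass_on_axis():
    pos, _ = init_rosette(600, 12.0)
    assert pos[:, 0].mean() == pytest.approx(6.0, abs=1e-9)
    assert pos[:, 1].mean() == pytest.approx(6.0, abs=1e-9)


def test_rosette_box_too_small():
    with pytest.raises(ValueError):
        init_rosette(100, 5.0)


# -- integrator basics ------------------------------------------------------


def _free_state(n, rng, spacing=5.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return SystemState(
        pos=pos, vel=maxwell_velocities(n, rng), box=np.full(3, 1e6),
        periodic=False, n_chain=0, types=np.zeros(n, dtype=np.int64),
        fene_bonds=np.empty((0, 2), dtype=np.int64),
    )


def test_zero_forces_zero_noise_uniform_motion(rng):
    state = _free_state(5, rng)
    v0 = state.vel.copy()
    p0 = state.pos.copy()
    integrate(state, 1000, thermostat=False, nonbonded=False, wall_k=0.0,
              kappa=0.0)
    assert np.allclose(state.vel, v0)
    assert np.allclose(state.pos, p0 + v0 * 1000 * 0.01)


def test_integrate_deterministic_under_seed(rng):
    def run(seed):
        r = np.random.default_rng(seed)
        state = _free_state(20, r)
        integrate(state, 500, True, r, nonbonded=False, wall_k=0.0, kappa=0.0)
        return state.pos.copy()

    assert (run(3) == run(3)).all()
    assert not np.allclose(run(3), run(4))


def test_fene_blowup_raises_diagnostic(rng):
    state = _free_state(2, rng, spacing=1.0)
    state.n_chain = 2
    state.fene_bonds = np.array([[0, 1]], dtype=np.int64)
    state.vel = np.array([[-40.0, 0, 0], [40.0, 0, 0]])
    with pytest.raises(RuntimeError, match="FENE bond blow-up"):
        integrate(state, 200, thermostat=False, nonbonded=False, wall_k=0.0)


# -- protein population -----------------------------------------------------


def test_tf_population_split_and_rounding():
    pop = TFPopulation.from_chain(2000)  # 200 proteins
    assert pop.total == 200
    assert pop.n_active == 50
    assert pop.n_polycomb == 25
    assert pop.n_hp1 == 125  # remainder goes to the largest share
    pop2 = TFPopulation.from_chain(150)
    assert pop2.total == 15
    assert (pop2.n_active, pop2.n_polycomb, pop2.n_hp1) == (3, 1, 11)


def test_tf_switching_frozen_at_zero_rate(rng):
    state = _free_state(10, rng)
    state.n_chain = 4
    state.tf_species = np.zeros(6, dtype=np.int64)
    state.tf_bound = np.array([True, False, True, False, True, False])
    before = state.tf_bound.copy()
    switch_tf_states(state, 1000.0, 0.0, rng)
    assert (state.tf_bound == before).all()


def test_tf_switching_stationary_half_bound(rng):
    state = _free_state(206, rng)
    state.n_chain = 6
    n_tf = 200
    state.tf_species = np.zeros(n_tf, dtype=np.int64)
    state.tf_bound = np.zeros(n_tf, dtype=bool)  # start all non-binding
    frac = []
    for _ in range(4000):
        switch_tf_states(state, 1.0, 1e-2, rng)
        frac.append(state.tf_bound.mean())
    assert np.mean(frac[1000:]) == pytest.approx(0.5, abs=0.02)


def test_tf_type_codes_follow_state(rng):
    state = _free_state(5, rng)
    state.n_chain = 2
    state.tf_species = np.array([0, 1, 2])
    state.tf_bound = np.array([True, False, True])
    state.update_tf_types()
    assert list(state.types[2:]) == [16, 20, 18]


# -- eps matrix -------------------------------------------------------------


def test_eps_matrix_values_and_symmetry():
    E = eps_matrix()
    assert (E == E.T).all()
    assert E[16, 1] == 7.0       # active(on) x atac
    assert E[16, 2] == 3.0       # active(on) x h3k27ac
    assert E[16, 3] == 7.0       # multi-mark bead: max rule
    assert E[17, 4] == 7.0       # polycomb(on) x h3k27me3
    assert E[18, 8] == 3.0       # hp1(on) x h3k9me3
    assert E[19, 1] == 0.0       # non-binding protein: steric
    assert E[16, 16] == 0.0      # protein-protein: steric
    assert E[0, 0] == 0.4        # unmarked chromatin self-attraction
    assert E[0, 2] == 0.0        # acetylated partner disables it
    assert E[1, 4] == 0.4        # atac x polycomb-marked: neither acetylated


def test_eps_matrix_stage_toggles():
    E0 = eps_matrix(chromatin_attraction=False, tf_attraction=False)
    assert (E0 == 0).all()
    E1 = eps_matrix(chromatin_attraction=True, tf_attraction=False)
    assert E1[0, 0] == 0.4 and E1[16, 1] == 0.0


# -- crumple rule -----------------------------------------------------------


def test_crumple_bonds_respect_acetylation():
    ac = np.zeros(10, dtype=bool)
    ac[4] = True
    bonds = crumple_bond_list(10, ac)
    pairs = {tuple(b) for b in bonds.tolist()}
    # bonds (2,4), (3,5), (4,6) all touch bead 4 -> removed
    assert (2, 4) not in pairs and (3, 5) not in pairs and (4, 6) not in pairs
    assert (0, 2) in pairs and (6, 8) in pairs
    assert len(crumple_bond_list(10)) == 8


# -- schedule / trajectory --------------------------------------------------


def test_schedule_desk_scaling_preserves_cadence():
    full = ProtocolSchedule()
    small = full.scaled(0.01)
    assert small.production == pytest.approx(3e3)
    assert small.cc_on_at == pytest.approx(1e2)
    assert small.tf_on_at == pytest.approx(5e2)
    # number of samples in the final window is scale-invariant
    assert small.sample_window / small.sample_every == pytest.approx(
        full.sample_window / full.sample_every)
    with pytest.raises(ValueError):
        full.scaled(0.0)


def test_schedule_full_scale_defaults():
    full = ProtocolSchedule()
    assert full.production == 3e5
    assert (full.cc_on_at, full.tf_on_at) == (1e4, 5e4)
    assert (full.rosette_relax, full.compress) == (600.0, 1e4)


def test_relaxation_protocol_deterministic_under_seed():
    """Identical seed => bit-identical relaxed conformations (full-pipeline
    determinism at a small desk scale)."""
    import tempfile

    from toposim.dynamics import run_relaxation
    from toposim.fixtures import (
        SyntheticLocusSpec,
        annotate_locus_dir,
        synth_epigenome,
    )

    spec = SyntheticLocusSpec(length_kbp=60, h3k27ac_blocks=[(20_000, 30_000)])
    with tempfile.TemporaryDirectory() as d:
        synth_epigenome(spec, d)
        _, track = annotate_locus_dir(d)
    a = run_relaxation(track, seed=5, desk_scale=0.005)
    b = run_relaxation(track, seed=5, desk_scale=0.005)
    c = run_relaxation(track, seed=6, desk_scale=0.005)
    assert (a.pos == b.pos).all() and (a.vel == b.vel).all()
    assert not np.allclose(a.pos, c.pos)


def test_trajectory_save_load_round_trip(tmp_path, rng):
    traj = Trajectory(
        frames=rng.random((5, 20, 3)), times=np.arange(5.0),
        box=np.array([10.0, 10.0, 10.0]), n_chain=16,
        metadata={"seed": 7, "desk_scale": 0.01},
    )
    path = tmp_path / "t.npz"
    traj.save(path)
    back = Trajectory.load(path)
    assert np.allclose(back.frames, traj.frames)
    assert back.n_chain == 16
    assert back.metadata["seed"] == 7
    assert back.chromatin().shape == (5, 16, 3)
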