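"""Read sampling, binning, ICE balancing, Pearson and directionality score."""

import numpy as np
import pytest
from scipy import stats

from toposim.contacts import (
    ContactMap,
    bin_map,
    directionality_correlation,
    directionality_score,
    ice_normalize,
    map_correlation,
    pairwise_acceptance,
    read_dense_tsv,
    read_triplets,
    sample_reads,
    write_dense_tsv,
    write_triplets,
)


def test_acceptance_probability_reference_points():
    assert pairwise_acceptance(0.0, 3.5) == 1.0
    assert pairwise_acceptance(3.5, 3.5) == pytest.approx(np.exp(-1))
    assert pairwise_acceptance(1.5, 1.5) == pytest.approx(np.exp(-1))


def test_sample_reads_symmetric_and_exact_total(rng):
    ens = rng.random((10, 30, 3)) * 5
    cmap = sample_reads(ens, 5000, rt=3.5, rng=rng)
    assert (cmap.matrix == cmap.matrix.T).all()
    assert cmap.total_reads == 5000
    assert np.trace(cmap.matrix) == 0  # self-pairs excluded


def test_sample_reads_unbiased_against_expectation():
    """Counts are proportional to the ensemble-mean acceptance probability
    (chi-square goodness of fit on a small toy ensemble)."""
    rng = np.random.default_rng(0)
    n = 12
    ens = rng.random((40, n, 3)) * 4
    cmap = sample_reads(ens, 200_000, rt=3.5, rng=rng)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(ens[:, iu] - ens[:, ju], axis=2)
    expected = np.exp(-d / 3.5).mean(axis=0)
    expected = expected / expected.sum() * 200_000
    observed = cmap.matrix[iu, ju]
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=len(expected) - 1)
    assert p > 0.01


def test_sample_reads_validates_inputs(rng):
    with pytest.raises(ValueError):
        sample_reads(np.empty((0, 5, 3)), 10, rng=rng)
    with pytest.raises(ValueError):
        sample_reads(rng.random((2, 5, 3)), 10, rt=0.0, rng=rng)


def test_bin_map_conserves_reads(rng):
    ens = rng.random((5, 40, 3)) * 6
    cmap = sample_reads(ens, 10_000, rng=rng)
    coarse = bin_map(cmap, 10)
    assert coarse.matrix.sum() == cmap.matrix.sum()
    assert coarse.n_bins == 4
    assert bin_map(cmap, 1).matrix.sum() == cmap.matrix.sum()


def test_bin_map_index_arithmetic():
    m = np.zeros((30, 30))
    m[3, 27] = m[27, 3] = 1.0
    coarse = bin_map(ContactMap(m), 10)
    assert coarse.matrix[0, 2] == 1.0
    assert coarse.matrix[2, 0] == 1.0
    with pytest.raises(ValueError):
        bin_map(coarse, 25)  # 25 not a multiple of the 10 kbp source bin


def test_ice_balances_random_matrix(rng):
    m = rng.random((20, 20)) + 0.05
    m = m + m.T
    iced = ice_normalize(ContactMap(m))
    sums = iced.matrix.sum(axis=1)
    assert np.std(sums) / np.mean(sums) < 1e-6
    assert iced.normalization == "ICE"


def test_ice_fixed_points():
    flat = ContactMap(np.full((4, 4), 2.0))
    iced = ice_normalize(flat)
    ratio = iced.matrix / flat.matrix
    assert np.allclose(ratio, ratio[0, 0])  # unchanged up to global scale


def test_ice_masks_empty_bins(rng):
    m = rng.random((10, 10)) + 0.1
    m = m + m.T
    m[3, :] = 0.0
    m[:, 3] = 0.0
    iced = ice_normalize(ContactMap(m))
    assert iced.mask[3]
    active = np.delete(np.arange(10), 3)
    sums = iced.matrix[active].sum(axis=1)
    assert np.std(sums) / np.mean(sums) < 1e-6


def test_map_correlation_self_and_inverse(rng):
    m = rng.random((15, 15))
    m = m + m.T
    a = ContactMap(m)
    r, p = map_correlation(a, a)
    assert r == pytest.approx(1.0)
    b = ContactMap(m.max() - m + 0.01)
    r2, _ = map_correlation(a, b)
    assert r2 < 0


def test_map_correlation_needs_pairs():
    tiny = ContactMap(np.ones((2, 2)))
    with pytest.raises(ValueError):
        map_correlation(tiny, tiny, exclude_band_bins=2)


def test_map_correlation_null(rng):
    a = ContactMap(_sym(rng.poisson(5.0, (30, 30))))
    b = ContactMap(_sym(rng.poisson(5.0, (30, 30))))
    r, p = map_correlation(a, b)
    assert abs(r) < 0.2


def _sym(m):
    m = np.asarray(m, dtype=float)
    return (m + m.T) / 2


def _distance_only_map(n, bin_kb=10):
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return ContactMap(1000.0 / (1.0 + abs(i - j)), bin_kb=bin_kb)


def test_dscore_zero_for_translation_invariant_map():
    cmap = _distance_only_map(120)
    D, untrunc = directionality_score(cmap)
    assert untrunc.sum() > 10
    assert np.allclose(D[untrunc], 0.0, atol=1e-9)


def test_dscore_sign_convention_left_block():
    """A strong contact block on the left of a bin makes D positive there."""
    n = 120
    m = np.ones((n, n))
    m[40:50, :] += 50.0
    m[:, 40:50] += 50.0
    cmap = ContactMap(_sym(m), bin_kb=10)
    D, untrunc = directionality_score(cmap)
    probe = 55  # block is within [probe-upper, probe-lower] on the left only
    assert untrunc[probe]
    assert D[probe] > 0


def test_dscore_mirror_antisymmetry(rng):
    m = _sym(rng.random((100, 100)))
    cmap = ContactMap(m, bin_kb=10)
    mirrored = ContactMap(m[::-1, ::-1].copy(), bin_kb=10)
    D, _ = directionality_score(cmap)
    Dm, _ = directionality_score(mirrored)
    assert np.allclose(Dm, -D[::-1], atol=1e-9)


def test_dscore_window_validation():
    cmap = _distance_only_map(120)
    with pytest.raises(ValueError):
        directionality_score(cmap, lower_kb=500, upper_kb=100)
    with pytest.raises(ValueError):
        directionality_score(_distance_only_map(3), lower_kb=20, upper_kb=500)


def test_directionality_correlation_identity_and_mirror(rng):
    # 150 bins of 10 kbp leave interior bins with untruncated 500 kbp windows
    m = _sym(rng.random((150, 150))) + 1.0
    m[30:40] += 5.0
    m[:, 30:40] += 5.0
    a = ContactMap(_sym(m), bin_kb=10)
    r, _ = directionality_correlation(a, a)
    assert r == pytest.approx(1.0)
    # mirror relation: D'(i) = -D(n-1-i), so the cross-correlation equals
    # minus the autocorrelation of D under reflection (computed independently)
    mirrored = ContactMap(a.matrix[::-1, ::-1].copy(), bin_kb=10)
    rm, _ = directionality_correlation(a, mirrored)
    D, ok = directionality_score(a)
    expected = -stats.pearsonr(D[ok], D[::-1][ok]).statistic
    assert rm == pytest.approx(expected, abs=1e-9)


def test_contact_map_validation():
    with pytest.raises(ValueError):
        ContactMap(np.arange(6.0).reshape(2, 3))
    with pytest.raises(ValueError):
        ContactMap(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        ContactMap(-np.ones((3, 3)))


def test_dense_tsv_round_trip(tmp_path, rng):
    cmap = ContactMap(_sym(rng.random((12, 12))), bin_kb=10, chrom="chrT")
    path = tmp_path / "m.tsv"
    write_dense_tsv(cmap, path)
    back = read_dense_tsv(path)
    assert np.allclose(back.matrix, cmap.matrix, atol=1e-6)
    assert back.bin_kb == 10 and back.chrom == "chrT"


def test_triplet_round_trip(tmp_path, rng):
    m = _sym(rng.poisson(2.0, (15, 15)))
    cmap = ContactMap(m)
    path = tmp_path / "m.triplets"
    write_triplets(cmap, path)
    back = read_triplets(path)
    assert np.allclose(back.matrix, cmap.matrix)
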