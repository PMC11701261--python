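"""Partner/influential calling, topos extent, network catalogs, diversity."""

import math

import numpy as np
import pytest

from toposim.annotation import GenomeFragment
from toposim.fixtures import toy_ensemble
from toposim.topos import (
    NetworkCatalog,
    ToposReport,
    build_report,
    call_influential,
    call_partners,
    contact_frequency,
    diversity_score,
    diversity_vs_influential,
    enumerate_networks,
    topos_extent,
)


@pytest.fixture()
def frag():
    return GenomeFragment("chrT", 0, 400_000)


def test_contact_frequency_exact_by_construction():
    ens = toy_ensemble(600, 50, promoter_bead=25,
                       contact_counts={10: 60, 30: 300, 40: 600})
    freqs = contact_frequency(ens, 25, [10, 30, 40])
    assert freqs == {10: pytest.approx(0.10), 30: pytest.approx(0.50),
                     40: pytest.approx(1.0)}


def test_contact_frequency_monotone_in_threshold():
    rng = np.random.default_rng(0)
    ens = rng.random((50, 20, 3)) * 6
    f1 = contact_frequency(ens, 5, range(10), threshold=2.0)
    f2 = contact_frequency(ens, 5, range(10), threshold=3.5)
    assert all(f2[b] >= f1[b] for b in f1)


def test_contact_frequency_validation():
    with pytest.raises(ValueError):
        contact_frequency(np.empty((0, 5, 3)), 0, [1])
    assert contact_frequency(np.zeros((3, 5, 3)), 0, []) == {}


def test_partner_threshold_inclusive_boundary():
    freqs = {1: 60 / 600, 2: 59 / 600, 3: 0.5}
    partners = call_partners(freqs)
    assert partners == {1, 3}  # exactly 10% is a partner, 59/600 is not


def test_influential_threshold_inclusive_boundary():
    freqs = {1: 300 / 600, 2: 0.49, 3: 0.9}
    assert call_influential(freqs) == {1, 3}
    # influential set is always a subset of the partner set
    assert call_influential(freqs) <= call_partners(freqs)


def test_topos_extent_span_and_degenerate(frag):
    (start, end), size = topos_extent(200, [100, 300], frag)
    assert (start, end) == (100_000, 301_000)
    assert size == 201.0
    (s2, e2), size2 = topos_extent(200, [], frag)
    assert (s2, e2) == (200_000, 201_000)
    assert size2 == 1.0
    assert topos_extent(200, [300, 100], frag) == topos_extent(200, [100, 300], frag)


def test_enumerate_networks_matches_brute_force():
    subsets = [set(), {3}, {3, 7}, {7}, {3}, {3, 7, 9}, set(), {9},
               {3}, {3, 7}, {9}, {3, 7, 9}, {7}, set(), {3}, {3},
               {9}, {3, 7}, set(), {3, 7, 9}]
    ens = toy_ensemble(20, 12, promoter_bead=0, subsets=subsets)
    catalog = enumerate_networks(ens, 0, [3, 7, 9])
    # independent recount straight from the declared plan
    expected = {}
    for sub in subsets:
        key = frozenset(sub)
        expected[key] = expected.get(key, 0) + 1
    assert catalog.counts == expected
    assert catalog.N == len(expected)
    assert sum(catalog.fractions.values()) == pytest.approx(1.0)


def test_network_count_bounded_by_2q():
    rng = np.random.default_rng(5)
    subsets = [set(np.flatnonzero(rng.random(3) < 0.5) + 1) for _ in range(200)]
    ens = toy_ensemble(200, 8, promoter_bead=0, subsets=subsets)
    catalog = enumerate_networks(ens, 0, [1, 2, 3])
    assert catalog.N <= 2 ** 3
    assert catalog.N <= 200


def test_all_structures_identical_single_network():
    ens = toy_ensemble(30, 8, promoter_bead=0, subsets=[{2, 4}] * 30)
    catalog = enumerate_networks(ens, 0, [2, 4])
    assert catalog.N == 1


def test_diversity_reference_values():
    single = NetworkCatalog({frozenset({1}): 10}, 10)
    assert diversity_score(single, q=1) == 0.0
    # no partners: well-defined, zero
    empty = NetworkCatalog({frozenset(): 5}, 5)
    assert diversity_score(empty, q=0) == 0.0
    # uniform over 4 networks at q=3: H = ln(4)/4
    uniform = NetworkCatalog(
        {frozenset(): 25, frozenset({1}): 25, frozenset({2}): 25,
         frozenset({1, 2}): 25}, 100)
    assert diversity_score(uniform, q=3) == pytest.approx(math.log(4) / 4, abs=1e-9)
    assert diversity_score(uniform, q=3) == pytest.approx(0.3466, abs=1e-4)


@pytest.mark.parametrize("q", [1, 2, 3])
def test_uniform_full_occupancy_entropy_q_ln2(q):
    n_networks = 2 ** q
    fracs = [1.0 / n_networks] * n_networks
    H = diversity_score(fracs, q)
    assert H * (q + 1) == pytest.approx(q * math.log(2), rel=1e-9)


def test_diversity_upper_bound_attained_only_uniform():
    # bound ln(min(2^q, n_structures))/(q+1)
    q, n = 3, 6
    uniform = [1 / n] * n
    H_uniform = diversity_score(uniform, q)
    assert H_uniform == pytest.approx(math.log(n) / (q + 1), rel=1e-9)
    skewed = [0.5, 0.1, 0.1, 0.1, 0.1, 0.1]
    assert diversity_score(skewed, q) < H_uniform


def test_diversity_validates_fractions():
    with pytest.raises(ValueError):
        diversity_score([0.5, 0.4], q=2)
    with pytest.raises(ValueError):
        diversity_score([0.5, 0.5], q=-1)


def _fake_report(gene, q, n_influential, H, frag):
    partners = list(range(10, 10 + q))
    return ToposReport(
        gene=gene, promoter_bead=5,
        frequencies={b: 0.6 for b in partners},
        partners=partners,
        influential=partners[:n_influential],
        extent_bp=(0, 1000), size_kbp=1.0,
        catalog=NetworkCatalog({frozenset(): 1}, 1), H=H,
    )


def test_diversity_vs_influential_planted_signal(frag):
    rng = np.random.default_rng(2)
    reports = []
    for k in range(40):
        q = 8
        n_inf = 1 + k % 7
        H = 0.05 * n_inf + rng.normal(0, 0.02)
        reports.append(_fake_report(f"g{k}", q, n_inf, H, frag))
    res = diversity_vs_influential(reports)
    r, p = res["overall"]
    assert r > 0.5 and p < 0.05
    # permuting H across reports destroys the correlation
    Hs = [r_.H for r_ in reports]
    rng.shuffle(Hs)
    shuffled = [_fake_report(f"s{k}", 8, 1 + k % 7, Hs[k], frag)
                for k in range(40)]
    r_null, _ = diversity_vs_influential(shuffled)["overall"]
    assert abs(r_null) < 0.35


def test_diversity_vs_influential_filters_and_errors(frag):
    # all-influential and zero-influential reports are filtered out
    reports = [_fake_report(f"g{k}", 4, 4, 0.1, frag) for k in range(20)]
    with pytest.raises(ValueError):
        diversity_vs_influential(reports)
    degenerate = [_fake_report(f"g{k}", 4, 2, 0.1, frag) for k in range(20)]
    res = diversity_vs_influential(degenerate)
    assert res["degenerate"]


def test_build_report_end_to_end_oracle(frag):
    ens = toy_ensemble(100, 60, promoter_bead=30,
                       contact_counts={10: 60, 20: 12, 50: 5})
    report = build_report(ens, frag, "gX", 30, [10, 20, 50])
    assert report.partners == [10, 20]
    assert report.influential == [10]
    assert report.q == 2
    assert report.size_kbp == 21.0
    assert report.catalog.N <= 4
    assert 0.0 <= report.H <= math.log(min(4, 100)) / 3
    d = report.to_json_dict()
    assert d["gene"] == "gX" and d["q"] == 2
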