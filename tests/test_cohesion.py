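import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genesetnet.cohesion import (
    CohesionRecord,
    CohesionUndefinedError,
    FitError,
    NetworkBackground,
    apply_normalizer,
    coco_score,
    cohesion_from_counts,
    cp50,
    fit_size_normalizer,
    ncoco_score,
    observed_pairs,
    observed_trios,
    read_cohesion_csv,
    score_corpus,
    theoretical_pairs,
    theoretical_trios,
    write_cohesion_csv,
)
from genesetnet.synthetic import synth_cohesion_records

from conftest import make_network, make_set


# ---- combinatorics ----


@pytest.mark.parametrize("n,expected", [(6, 15), (101, 5050), (1, 0), (0, 0), (2, 1)])
def test_theoretical_pairs(n, expected):
    assert theoretical_pairs(n) == expected


@pytest.mark.parametrize("n,expected", [(3, 1), (4, 4), (2, 0), (1, 0), (6, 20)])
def test_theoretical_trios(n, expected):
    assert theoretical_trios(n) == expected


def test_negative_size_rejected():
    with pytest.raises(ValueError):
        theoretical_pairs(-1)
    with pytest.raises(ValueError):
        theoretical_trios(-2)


# ---- coverage counting ----


def test_observed_pairs_complete_graph(k4_network):
    gs = make_set("S", ["A", "B", "C", "D"])
    assert observed_pairs(gs, k4_network) == 6


def test_observed_pairs_no_edges(k4_network):
    gs = make_set("S", ["X", "Y"])
    assert observed_pairs(gs, k4_network) == 0


def test_observed_trios_complete_graph(k4_network):
    gs = make_set("S", ["A", "B", "C", "D"])
    assert observed_trios(gs, k4_network) == 4  # C(4,3)


def test_observed_trios_path_is_zero():
    net = make_network([("A", "B"), ("B", "C")])
    gs = make_set("S", ["A", "B", "C"])
    assert observed_trios(gs, net) == 0


def _brute_pairs(members, net, min_conf):
    return sum(
        1
        for a, b in itertools.combinations(sorted(members), 2)
        if net.has_edge(a, b, min_conf)
    )


def _brute_trios(members, net, min_conf):
    return sum(
        1
        for a, b, c in itertools.combinations(sorted(members), 3)
        if net.has_edge(a, b, min_conf)
        and net.has_edge(b, c, min_conf)
        and net.has_edge(a, c, min_conf)
    )


@pytest.mark.parametrize("min_conf", [0.0, 0.6, 0.9])
def test_coverage_vs_brute_force_enumeration(min_conf):
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(30)]
    net = make_network(
        (genes[i], genes[j], float(rng.uniform(0, 1)))
        for i in range(30)
        for j in range(i + 1, 30)
        if rng.random() < 0.3
    )
    members = rng.choice(genes, size=20, replace=False).tolist()
    gs = make_set("S", members)
    assert observed_pairs(gs, net, min_conf) == _brute_pairs(members, net, min_conf)
    assert observed_trios(gs, net, min_conf) == _brute_trios(members, net, min_conf)


def test_coverage_bounded_by_theoretical(ref_data):
    for gs in ref_data.corpus:
        if gs.size < 2:
            continue
        for mc in (0.0, 0.7, 0.95):
            assert 0 <= observed_pairs(gs, ref_data.ppi, mc) <= theoretical_pairs(gs.size)
            assert 0 <= observed_trios(gs, ref_data.ppi, mc) <= theoretical_trios(gs.size)


def test_raising_cutoff_never_increases_coverage(ref_data):
    gs = next(s for s in ref_data.corpus if s.size >= 10)
    cuts = [0.0, 0.3, 0.6, 0.8, 0.95, 1.0]
    pairs = [observed_pairs(gs, ref_data.ppi, c) for c in cuts]
    trios = [observed_trios(gs, ref_data.ppi, c) for c in cuts]
    assert pairs == sorted(pairs, reverse=True)
    assert trios == sorted(trios, reverse=True)


# ---- cohesion score ----


def _exact_upper_tail(k, M, K, n):
    """Exact hypergeometric upper tail via rational combinatorics."""
    if k <= 0:
        return Fraction(1)
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return total


def test_coco_zero_coverage_is_zero():
    bg = NetworkBackground(n_genes=100, n_edges=50, n_triangles=10)
    assert cohesion_from_counts(0, 15, 0, 20, bg) == 0.0


def test_coco_monotone_in_added_edge():
    genes = [f"G{i}" for i in range(12)]
    edges = [("G0", "G1", 1.0), ("G2", "G3", 1.0), ("G5", "G9", 1.0)]
    net1 = make_network(edges)
    net2 = make_network(edges + [("G0", "G2", 1.0)])
    gs = make_set("S", genes[:5])
    bg1 = NetworkBackground.from_network(net1, genes)
    bg2 = NetworkBackground(bg1.n_genes, bg1.n_edges, bg1.n_triangles)
    # same background: one extra within-set edge cannot lower the score
    assert coco_score(gs, net2, bg2) >= coco_score(gs, net1, bg1)


def test_s2_matches_exact_enumeration_small_universe():
    # N=10 genes; compare the pair-sampling tail with exact rational arithmetic
    N, E = 10, 17
    bg = NetworkBackground(n_genes=N, n_edges=E, n_triangles=0)
    M = theoretical_pairs(N)  # 45
    for size in (3, 5, 7):
        t = theoretical_pairs(size)
        for k in range(0, t + 1):
            expected = _exact_upper_tail(k, M, E, t)
            got = cohesion_from_counts(k, t, 0, theoretical_trios(size), bg)
            want = -math.log10(float(expected)) if expected > 0 else 320.0
            assert got == pytest.approx(want, abs=1e-9)


def test_s3_matches_exact_enumeration_small_universe():
    N, T = 12, 30
    bg = NetworkBackground(n_genes=N, n_edges=0, n_triangles=T)
    M3 = theoretical_trios(N)  # 220
    t3 = theoretical_trios(5)  # 10
    for k in range(0, t3 + 1):
        expected = _exact_upper_tail(k, M3, T, t3)
        got = cohesion_from_counts(0, theoretical_pairs(5), k, t3, bg)
        want = -math.log10(float(expected)) if expected > 0 else 320.0
        assert got == pytest.approx(want, abs=1e-9)


def test_coco_singleton_undefined(k4_network):
    bg = NetworkBackground.from_network(k4_network, "ABCDXY")
    with pytest.raises(CohesionUndefinedError):
        coco_score(make_set("S", ["A"]), k4_network, bg)


def test_coco_empty_network_is_zero():
    from genesetnet.corpus_io import InteractionNetwork

    net = InteractionNetwork()
    bg = NetworkBackground.from_network(net, ["A", "B", "C"])
    assert coco_score(make_set("S", ["A", "B"]), net, bg) == 0.0


def test_coco_capped_at_640():
    bg = NetworkBackground(n_genes=20000, n_edges=300000, n_triangles=100000)
    score = cohesion_from_counts(5050, 5050, 1000, 171700, bg)
    assert score <= 640.0  # 320 per term


# ---- size normalizer ----


def _record(set_id, n, coco):
    return CohesionRecord(
        set_id=set_id,
        n=n,
        theoretical_pairs=theoretical_pairs(n),
        observed_pairs=0,
        theoretical_trios=theoretical_trios(n),
        observed_trios=0,
        coco=coco,
    )


def test_fit_exact_polynomial():
    records = [_record(f"S{n}", n, float(n) ** 2) for n in (2, 4, 8, 16, 32)]
    norm = fit_size_normalizer(records, degree=1)
    # log2(coco) = 2*log2(n): intercept 0, slope 2
    assert norm.coefficients == pytest.approx([0.0, 2.0], abs=1e-9)


def test_fit_degree_zero_is_mean():
    records = [_record(f"S{n}", n, c) for n, c in [(2, 4.0), (4, 16.0), (8, 2.0)]]
    norm = fit_size_normalizer(records, degree=0)
    assert norm.coefficients[0] == pytest.approx(
        np.mean([np.log2(4.0), np.log2(16.0), np.log2(2.0)]), abs=1e-12
    )


def test_fit_too_few_records():
    with pytest.raises(FitError):
        fit_size_normalizer([_record("S", 4, 2.0)], degree=1)


def test_fit_identical_sizes_rank_deficient():
    records = [_record(f"S{i}", 8, float(i + 1)) for i in range(10)]
    with pytest.raises(FitError, match="rank-deficient"):
        fit_size_normalizer(records, degree=1)


def test_fit_excludes_zero_scores():
    records = [_record(f"S{n}", n, float(n) ** 2) for n in (2, 4, 8, 16, 32)]
    records += [_record("Z1", 64, 0.0), _record("Z2", 128, 0.0)]
    norm = fit_size_normalizer(records, degree=1)
    assert norm.coefficients == pytest.approx([0.0, 2.0], abs=1e-9)


def test_fit_simulation_recovery_within_3se():
    rng = np.random.default_rng(11)
    truth = np.array([0.5, 1.2, -0.05, 0.01])  # ascending powers
    sizes = np.unique(np.round(2.0 ** rng.uniform(1, 10, size=2500))).astype(int)
    x = np.log2(sizes)  # exact log-sizes of the integer sizes stored
    y = np.polynomial.polynomial.polyval(x, truth) + rng.normal(0, 0.1, size=x.size)
    records = [
        _record(f"S{i}", int(n), float(2.0**yi))
        for i, (n, yi) in enumerate(zip(sizes, y))
    ]
    xr = np.log2([r.n for r in records])
    yr = np.log2([r.coco for r in records])
    norm = fit_size_normalizer(records, degree=3)
    X = np.vander(xr, 4, increasing=True)
    resid = yr - X @ norm.coefficients
    sigma2 = resid @ resid / (len(xr) - 4)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    assert np.all(np.abs(norm.coefficients - truth) < 3 * se)


def test_ncoco_on_trend_is_reference_level():
    records = [_record(f"S{n}", n, float(n) ** 2) for n in (2, 4, 8, 16, 32)]
    norm = fit_size_normalizer(records, degree=1)
    vals = {ncoco_score(r.coco, r.n, norm) for r in records}
    for v in vals:
        assert v == pytest.approx(2.0**norm.reference_level, rel=1e-9)


def test_ncoco_flat_trend_identity():
    records = [_record(f"S{n}", n, 7.0) for n in (2, 4, 8, 16)]
    norm = fit_size_normalizer(records, degree=0)
    assert ncoco_score(7.0, 100, norm) == pytest.approx(7.0, rel=1e-12)


def test_ncoco_zero_score_maps_to_zero():
    records = [_record(f"S{n}", n, float(n)) for n in (2, 4, 8)]
    norm = fit_size_normalizer(records, degree=0)
    assert ncoco_score(0.0, 10, norm) == 0.0


def test_ncoco_invalid_inputs():
    records = [_record(f"S{n}", n, float(n)) for n in (2, 4, 8)]
    norm = fit_size_normalizer(records, degree=0)
    with pytest.raises(ValueError):
        ncoco_score(-1.0, 10, norm)
    with pytest.raises(ValueError):
        ncoco_score(1.0, 1, norm)
    with pytest.raises(ValueError):
        ncoco_score(1.0, 10, None)


def test_ncoco_decorrelates_size():
    from scipy.stats import spearmanr

    records = synth_cohesion_records(seed=5, n_sets=600)
    norm = fit_size_normalizer(records, degree=3)
    apply_normalizer(records, norm)
    sizes = [r.n for r in records]
    rho_raw = spearmanr(sizes, [r.coco for r in records]).statistic
    rho_norm = spearmanr(sizes, [r.ncoco for r in records]).statistic
    assert abs(rho_raw) > 0.6
    assert abs(rho_norm) < 0.1


def test_normalizer_json_round_trip(tmp_path):
    records = [_record(f"S{n}", n, float(n) ** 2) for n in (2, 4, 8, 16, 32)]
    norm = fit_size_normalizer(records, degree=1)
    norm.to_json(tmp_path / "n.json")
    from genesetnet.cohesion import SizeNormalizer

    back = SizeNormalizer.from_json(tmp_path / "n.json")
    assert back.degree == norm.degree
    assert back.coefficients == pytest.approx(norm.coefficients)
    assert back.reference_level == pytest.approx(norm.reference_level)


# ---- CP50 ----


def test_cp50_examples():
    assert cp50([1, 2, 3]) == 2
    assert cp50([1, 2, 3, 4]) == 2  # lower interpolation


def test_cp50_matches_sort_index_oracle():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 1, size=1000).tolist()
    expected = sorted(vals)[int(0.5 * (len(vals) - 1))]
    assert cp50(vals) == expected


def test_cp50_groups_and_empty():
    out = cp50([1, 2, 3, 10, 20], ["a", "a", "a", "b", "b"])
    assert out == {"a": 2, "b": 10}
    with pytest.raises(ValueError):
        cp50([])


# ---- corpus scoring & CSV ----


def test_score_corpus_skips_singletons(ref_data):
    records = score_corpus(ref_data.corpus, ref_data.ppi)
    scored = {r.set_id for r in records}
    for gs in ref_data.corpus:
        assert (gs.id in scored) == (gs.size >= 2)


def test_cohesion_csv_round_trip(tmp_path, ref_data):
    records = score_corpus(ref_data.corpus, ref_data.ppi)
    norm = fit_size_normalizer(records, degree=2)
    apply_normalizer(records, norm)
    write_cohesion_csv(records, tmp_path / "c.csv")
    back = read_cohesion_csv(tmp_path / "c.csv")
    assert [r.set_id for r in back] == [r.set_id for r in records]
    for a, b in zip(records, back):
        assert b.coco == pytest.approx(a.coco, rel=1e-9)
        assert b.ncoco == pytest.approx(a.ncoco, rel=1e-9)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=400))
def test_neg_log_tail_monotone_in_k(k):
    bg = NetworkBackground(n_genes=100, n_edges=800, n_triangles=0)
    a = cohesion_from_counts(k, 400, 0, 0, bg)
    b = cohesion_from_counts(k + 1, 400, 0, 0, bg)
    assert b >= a - 1e-12
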