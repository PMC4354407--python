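import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from methloess import (
    HousekeepingSet,
    Measure,
    MethylationMatrix,
    permutation_overlap_baseline,
    replicate_correlation,
    run_benchmark_suite,
    split_half_concordance,
    trait_correlation,
    win_decline_counts,
)
from methloess.simulate import SimulationConfig, simulate_array_set, write_fixture


def _mm(values, samples=None, measure=Measure.M_VALUE):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    probes = pd.Index([f"cg{i:04d}" for i in range(values.shape[0])])
    return MethylationMatrix(values, measure, probes, samples)


# ---------------------------------------------------------------------------
# benchmark 1
# ---------------------------------------------------------------------------

def test_self_replicate_has_unit_correlation():
    rng = np.random.default_rng(0)
    col = rng.normal(size=200)
    mm = _mm(np.column_stack([col, col]))
    corr = replicate_correlation(mm, [("s0", "s1")])
    assert corr.iloc[0] == pytest.approx(1.0)


def test_constant_shift_leaves_pearson_unchanged():
    rng = np.random.default_rng(1)
    col = rng.normal(size=200)
    mm = _mm(np.column_stack([col, col + 2.5]))
    assert replicate_correlation(mm, [("s0", "s1")]).iloc[0] == pytest.approx(1.0)


def test_correlation_matches_direct_formula():
    rng = np.random.default_rng(2)
    x = rng.normal(size=1000)
    y = 0.8 * x + rng.normal(size=1000)
    mm = _mm(np.column_stack([x, y]))
    got = replicate_correlation(mm, [("s0", "s1")]).iloc[0]
    expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert got == pytest.approx(expected, abs=1e-12)


def test_correlation_excludes_missing_pairwise_and_errors_when_sparse():
    rng = np.random.default_rng(3)
    x = rng.normal(size=300)
    y = x + rng.normal(0, 0.1, 300)
    x[:50] = np.nan
    y[50:100] = np.nan
    mm = _mm(np.column_stack([x, y]))
    ok = np.isfinite(x) & np.isfinite(y)
    expected = np.corrcoef(x[ok], y[ok])[0, 1]
    assert replicate_correlation(mm, [("s0", "s1")]).iloc[0] == pytest.approx(expected)
    with pytest.raises(ValueError, match="< 250"):
        replicate_correlation(mm, [("s0", "s1")], min_shared=250)


def test_win_decline_counts_by_exhaustive_enumeration():
    raw = pd.Series({"p1": 0.90, "p2": 0.80, "p3": 0.70})
    methods = {
        "A": pd.Series({"p1": 0.95, "p2": 0.85, "p3": 0.60}),
        "B": pd.Series({"p1": 0.95, "p2": 0.75, "p3": 0.65}),
    }
    out = win_decline_counts(raw, methods)
    # p1: A and B tie for best (both count); p2: A best; p3: raw best
    assert out.loc["A", "n_best"] == 2
    assert out.loc["B", "n_best"] == 1
    assert out.loc["none", "n_best"] == 1
    assert out.loc["A", "n_declined"] == 1   # p3 only
    assert out.loc["B", "n_declined"] == 2   # p2 and p3
    assert out.loc["none", "n_declined"] == 0


def test_single_dominant_method_wins_everywhere():
    raw = pd.Series({"p1": 0.5, "p2": 0.6})
    out = win_decline_counts(raw, {"A": raw + 0.1})
    assert out.loc["A", "n_best"] == 2 and out.loc["A", "n_declined"] == 0


# ---------------------------------------------------------------------------
# benchmark 2
# ---------------------------------------------------------------------------

def _sex_cohort(n_probes=400, n_pairs=8, effect=2.0, seed=4, n_signal=10):
    """Two identical-by-construction halves plus planted sex effects."""
    rng = np.random.default_rng(seed)
    samples = [f"s{j}" for j in range(2 * n_pairs)]
    pairs = [(samples[2 * p], samples[2 * p + 1]) for p in range(n_pairs)]
    sexes = {}
    base = rng.normal(0, 1, size=(n_probes, n_pairs))
    noise = 0.2
    values = np.empty((n_probes, 2 * n_pairs))
    for p in range(n_pairs):
        sex = "M" if p % 2 else "F"
        sexes[samples[2 * p]] = sexes[samples[2 * p + 1]] = sex
        col = base[:, p].copy()
        if sex == "M":
            col[:n_signal] += effect
        values[:, 2 * p] = col + rng.normal(0, noise, n_probes)
        values[:, 2 * p + 1] = col + rng.normal(0, noise, n_probes)
    return _mm(values, samples), pairs, sexes


def test_identical_halves_give_full_overlap():
    mm, pairs, sexes = _sex_cohort(seed=5)
    # make the two halves exactly identical
    ident = mm.values.copy()
    for p in range(len(pairs)):
        ident[:, 2 * p + 1] = ident[:, 2 * p]
    mm2 = _mm(ident, list(mm.sample_ids))
    curve = split_half_concordance(mm2, pairs, sexes, k_max=50)
    assert (curve.values == 100.0).all()


def test_overlap_is_complete_at_full_probe_count():
    mm, pairs, sexes = _sex_cohort(n_probes=100, seed=6)
    curve = split_half_concordance(mm, pairs, sexes, k_max=100)
    assert curve.iloc[-1] == pytest.approx(100.0)


def test_planted_signal_found_above_permutation_baseline():
    mm, pairs, sexes = _sex_cohort(n_probes=500, n_signal=10, effect=3.0, seed=7)
    curve = split_half_concordance(mm, pairs, sexes, k_max=10)
    baseline = permutation_overlap_baseline(mm, pairs, sexes, k=10, n_permutations=10, seed=8)
    assert curve.iloc[-1] > baseline + 30.0


def test_ranking_invariant_under_affine_transform_of_m():
    mm, pairs, sexes = _sex_cohort(seed=9)
    curve1 = split_half_concordance(mm, pairs, sexes, k_max=30)
    mm_affine = _mm(3.5 * mm.values - 2.0, list(mm.sample_ids))
    curve2 = split_half_concordance(mm_affine, pairs, sexes, k_max=30)
    np.testing.assert_allclose(curve1.values, curve2.values)


def test_group_starved_half_errors():
    mm, pairs, sexes = _sex_cohort(n_pairs=2, seed=10)  # one F pair, one M pair
    with pytest.raises(ValueError, match="at least 2"):
        split_half_concordance(mm, pairs, sexes, k_max=5)


# ---------------------------------------------------------------------------
# benchmark 3
# ---------------------------------------------------------------------------

def test_monotone_relation_gives_unit_spearman():
    ages = {f"s{j}": 50.0 + j for j in range(6)}
    values = np.array([[0.1, 0.2, 0.3, 0.5, 0.7, 0.9]])
    mm = _mm(values, list(ages))
    assert trait_correlation(mm, "cg0000", ages) == pytest.approx(1.0)
    # invariance under a monotone transform of the trait
    squared = {k: v**2 for k, v in ages.items()}
    assert trait_correlation(mm, "cg0000", squared) == pytest.approx(1.0)


def test_spearman_matches_rank_formula_on_hand_table():
    trait = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
    row = np.array([[2.0, 1.0, 4.0, 3.0, 5.0]])
    mm = _mm(row, list(trait))
    got = trait_correlation(mm, "cg0000", trait)
    d = rankdata(row[0]) - rankdata(list(trait.values()))
    expected = 1 - 6 * (d**2).sum() / (5 * (5**2 - 1))
    assert got == pytest.approx(expected)
    assert got == pytest.approx(0.8)


def test_spearman_identical_on_m_and_beta_scales():
    from methloess.core import m_to_beta

    rng = np.random.default_rng(11)
    trait = {f"s{j}": float(v) for j, v in enumerate(rng.normal(size=10))}
    m_row = rng.normal(0, 2, size=(1, 10))
    mm_m = _mm(m_row, list(trait))
    mm_b = _mm(m_to_beta(m_row), list(trait), measure=Measure.BETA)
    assert trait_correlation(mm_m, "cg0000", trait) == pytest.approx(
        trait_correlation(mm_b, "cg0000", trait)
    )


def test_constant_trait_warns_and_returns_missing():
    trait = {f"s{j}": 1.0 for j in range(5)}
    mm = _mm(np.arange(5.0)[None, :], list(trait))
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(trait_correlation(mm, "cg0000", trait))


def test_too_few_complete_pairs_errors():
    trait = {"s0": 1.0, "s1": 2.0, "s2": np.nan, "s3": 4.0}
    mm = _mm(np.array([[0.1, np.nan, 0.3, np.nan]]), list(trait))
    with pytest.raises(ValueError, match="fewer than 3"):
        trait_correlation(mm, "cg0000", trait)


# ---------------------------------------------------------------------------
# the full suite
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def suite_fixture(tmp_path_factory):
    cfg = SimulationConfig(
        n_probes_p1g=400, n_probes_p1r=400, n_probes_p2=1600,
        n_samples=8, n_replicate_pairs=4, housekeeping_fraction=0.15,
        n_differential=15, n_trait_probes=8, seed=51,
    )
    aset, truth = simulate_array_set(cfg)
    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(aset, truth, directory)
    return directory


def test_suite_reports_all_cells(suite_fixture):
    result = run_benchmark_suite(suite_fixture, ("none", "loess", "qn1", "qn2"), k_max=50)
    assert set(result.replicate["method"]) == {"none", "loess", "qn1", "qn2"}
    assert set(result.replicate["probe_class"]) == {"P1", "P2"}
    assert set(result.replicate["measure"]) == {"m", "beta"}
    # 4 methods x 2 classes x 2 measures x 4 pairs
    assert len(result.replicate) == 64
    assert result.replicate["correlation"].between(-1, 1).all()
    assert len(result.win_decline) == 16  # incl. the raw "none" row per cell
    assert result.overlap["overlap_pct"].between(0, 100).all()
    assert set(result.trait["method"]) == {"none", "loess", "qn1", "qn2"}
    table = result.table()
    assert {"method", "benchmark", "probe_class", "measure", "statistic", "value"} == set(
        table.columns
    )


def test_suite_accepts_external_matrix_and_writes_table(suite_fixture, tmp_path):
    from methloess.simulate import read_fixture

    aset, _ = read_fixture(suite_fixture)
    external = {"shifted": _mm(aset.mvalues().values + 0.1, list(aset.sample_ids))}
    external["shifted"].probe_ids = aset.probe_ids
    result = run_benchmark_suite(suite_fixture, ("none", "shifted"), external=external, k_max=20)
    assert "shifted" in set(result.replicate["method"])
    out = result.write(tmp_path)
    assert out.exists() and out.stat().st_size > 0
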