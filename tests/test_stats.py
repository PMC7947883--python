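"""Summary statistics, paired tests and cohort report tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvconcord import (
    build_tables,
    compare_gtv_set,
    make_cohort,
    paired_t,
    spearman,
    summarize,
    wilcoxon_paired,
)
from gtvconcord.phantom import GroupPerturbationModel


# ---------------------------------------------------------- summarize ----

def test_summarize_closed_form():
    s = summarize([1, 2, 3, 4, 5])
    assert s.median == 3 and s.mean == 3
    assert s.sd == pytest.approx(np.sqrt(2.5))
    assert s.iqr == (2.0, 4.0)


def test_summarize_constant_list():
    s = summarize([4.2] * 7)
    assert s.sd == 0.0 and s.iqr == (4.2, 4.2) and s.median == 4.2


def test_summarize_matches_sort_based_oracle(rng):
    x = rng.normal(size=500)
    s = summarize(x)
    xs = np.sort(x)
    assert s.median == pytest.approx(0.5 * (xs[249] + xs[250]))
    # linear-interpolation quartiles from order statistics
    def q(p):
        h = (len(xs) - 1) * p
        lo = int(np.floor(h))
        return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])
    assert s.iqr == pytest.approx((q(0.25), q(0.75)))
    assert s.mean == pytest.approx(xs.mean())
    assert s.sd == pytest.approx(np.std(xs, ddof=1))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
def test_summarize_order_invariants(values):
    """q1 <= median <= q3 and min <= mean <= max for any sample."""
    s = summarize(values)
    assert s.iqr[0] <= s.median <= s.iqr[1]
    assert min(values) - 1e-9 <= s.mean <= max(values) + 1e-9
    assert s.n == len(values)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=4, max_size=40),
    st.integers(0, 2**31 - 1),
)
def test_wilcoxon_p_value_is_a_probability(a, salt):
    """Any paired sample yields p in [0,1] or an explicit degenerate flag."""
    rng = np.random.default_rng(salt)
    b = list(rng.normal(size=len(a)))
    res = wilcoxon_paired(a, b)
    assert res.degenerate or 0.0 <= res.p_value <= 1.0


def test_summarize_empty_raises():
    with pytest.raises(ValueError):
        summarize([])


# ------------------------------------------------------------ wilcoxon ----

def test_wilcoxon_identical_samples_degenerate():
    res = wilcoxon_paired([1, 2, 3], [1, 2, 3])
    assert res.degenerate and np.isnan(res.p_value)


def test_wilcoxon_exact_small_n_matches_enumeration():
    """n=6 uniformly signed differences: p = 2/2^6 by sign-flip enumeration."""
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0]
    res = wilcoxon_paired(a, b)
    assert res.p_value == pytest.approx(2 / 64)
    # independent oracle: enumerate all sign assignments of the rank sum
    d = np.array(a) - np.array(b)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks.sum()  # all positive
    count = 0
    for signs in itertools.product([0, 1], repeat=6):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, ranks.sum() - w) <= min(w_obs, ranks.sum() - w_obs):
            count += 1
    assert res.p_value == pytest.approx(count / 64)


def test_wilcoxon_switches_to_normal_approximation():
    rng = np.random.default_rng(0)
    a = rng.normal(size=40)
    b = rng.normal(size=40)
    res = wilcoxon_paired(a, b)
    assert res.note == "approx" and res.n_pairs == 40
    assert 0.0 <= res.p_value <= 1.0 and np.isfinite(res.statistic)


def test_wilcoxon_drops_zero_differences():
    a = [1.0, 2.0, 3.0, 3.0, 5.0, 7.0, 9.0]
    b = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 4.0]
    res = wilcoxon_paired(a, b)
    assert res.n_pairs == 4  # three zero differences removed


# ------------------------------------------------------------ paired t ----

def test_paired_t_zero_variance_degenerate():
    res = paired_t([2, 3, 4, 5], [1, 2, 3, 4])
    assert res.degenerate


def test_paired_t_closed_form():
    res = paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
    d = np.array([1.0, 2.0, 3.0, 4.0])
    expected = d.mean() / (d.std(ddof=1) / 2.0)
    assert res.statistic == pytest.approx(expected, abs=1e-3)
    assert res.statistic == pytest.approx(3.873, abs=1e-3)


# ------------------------------------------------------------ spearman ----

def test_spearman_monotone_signs():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert spearman(x, [2.0, 4.0, 5.0, 7.0, 11.0]).statistic == pytest.approx(1.0)
    assert spearman(x, [5.0, 4.0, 3.0, 2.0, 1.0]).statistic == pytest.approx(-1.0)


def test_spearman_constant_degenerate():
    assert spearman([1, 1, 1, 1], [1, 2, 3, 4]).degenerate


def test_ci_vector_negative_dependence_from_phantom(small_spec):
    """Larger displacement vectors come with lower conformity indices."""
    pts = make_cohort(10, 0, 10, seed=11, base_spec=small_spec)
    recs = [compare_gtv_set(p.gtv_set, p.id, p.group) for p in pts]
    key = "GTV_PET-reg and GTV_3D"
    ci = [r.overlaps[key].ci for r in recs]
    v = [r.displacements[key].vector_v for r in recs]
    assert spearman(ci, v).statistic < 0


# --------------------------------------------------------------- tables ----

@pytest.fixture(scope="module")
def small_cohort_records(small_spec):
    pts = make_cohort(4, 3, 2, seed=21, base_spec=small_spec)
    return [compare_gtv_set(p.gtv_set, p.id, p.group) for p in pts]


def test_build_tables_layout(small_cohort_records):
    res = build_tables(small_cohort_records)
    assert set(res.tables) == {
        "t2_vector_displacement", "t3_volume", "t4_length_diameter",
        "t5_ci", "t6_di",
    }
    t2 = res.tables["t2_vector_displacement"]
    assert set(t2["group"]) == {"Total", "A", "B", "C"}
    assert res.group_sizes == {"Total": 9, "A": 4, "B": 3, "C": 2}
    t6 = res.tables["t6_di"]
    assert len(t6[t6.group == "Total"]) == 6  # all six ordered DI entries


def test_zero_perturbation_cohort_tables(small_spec):
    null = {g: GroupPerturbationModel() for g in "ABC"}
    pts = make_cohort(2, 1, 1, distributions=null, seed=5, base_spec=small_spec)
    recs = [compare_gtv_set(p.gtv_set, p.id, p.group) for p in pts]
    res = build_tables(recs)
    t5 = res.tables["t5_ci"]
    assert (t5["median"] == 1.0).all() and (t5["mean"] == 1.0).all()
    t2 = res.tables["t2_vector_displacement"]
    assert (t2["mean_mm"] == 0.0).all()
    # identical pairs make every Wilcoxon comparison degenerate, and flagged
    assert all(v["degenerate"] for v in res.tests["t5_ci_tests"].values()
               if v["test"].startswith("wilcoxon"))


def test_single_patient_cohort_degenerate_tests(small_spec):
    pts = make_cohort(1, 0, 0, seed=2, base_spec=small_spec)
    recs = [compare_gtv_set(p.gtv_set, p.id, p.group) for p in pts]
    with pytest.warns(UserWarning):  # groups B and C have no records
        res = build_tables(recs)
    t5 = res.tables["t5_ci"]
    row = t5[(t5.group == "Total")].iloc[0]
    key = row["pair"]
    assert row["median"] == pytest.approx(recs[0].overlaps[key].ci)
    assert all(v["degenerate"] for v in res.tests["t2_vector_wilcoxon"].values())


def test_holm_adjustment_is_monotone(small_cohort_records):
    res = build_tables(small_cohort_records, holm=True)
    for block in res.tests.values():
        ps = [(v["p_value"], v["p_holm"]) for v in block.values()
              if v.get("p_holm") is not None]
        for p, padj in ps:
            assert padj >= p - 1e-15 and padj <= 1.0
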