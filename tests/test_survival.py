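"""Turnbull intervals, NPMLE, bootstrap median, permutation comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sitsim as s
from sitsim.survival import NonConvergenceError
from sitsim.synth import SurvivalGeneratorParams

INF = math.inf


def rec(left, right, group="g"):
    return s.IntervalRecord(group, left, right)


# ---------------------------------------------------------------------------
# Turnbull intervals
# ---------------------------------------------------------------------------

def test_single_interval_type():
    assert s.turnbull_intervals([rec(3, 6), rec(3, 6)]) == [(3, 6)]


def test_disjoint_inspection_windows():
    assert s.turnbull_intervals([rec(0, 3), rec(3, 6)]) == [(0, 3), (3, 6)]


def test_exact_plus_censored_mix_gives_point_intervals():
    out = s.turnbull_intervals([rec(5, 5), rec(2, 2), rec(7, INF)])
    assert out == [(2, 2), (5, 5), (7, INF)]


def test_overlapping_intervals_reduce_to_intersection():
    # (2,6] and (4,8] can only place mass on their intersection (4,6]
    assert s.turnbull_intervals([rec(2, 6), rec(4, 8)]) == [(4, 6)]


def _key(v, open_left=False):
    return (v, 1 if open_left else 0)


def _as_keys(l, r):
    """(lo_key, hi_key) representation of (l, r] or a point [t, t]."""
    if l == r:
        return _key(l), _key(r)
    return _key(l, open_left=True), _key(r)


@given(
    st.lists(
        st.tuples(st.integers(0, 8), st.integers(1, 5), st.booleans()),
        min_size=1,
        max_size=8,
    )
)
@settings(max_examples=100)
def test_turnbull_intervals_are_maximal_intersections(spec):
    """Brute-force oracle: every returned interval is contained in, or
    disjoint from, each record; every record contains one; and no gap
    between records hides a missed candidate interval."""
    records = []
    for left, width, exact in spec:
        if exact:
            records.append(rec(left, left))
        else:
            records.append(rec(left, left + width))
    intervals = s.turnbull_intervals(records)

    rec_keys = [
        _as_keys(r.left, r.right if not math.isinf(r.right) else 1e9)
        for r in records
    ]
    int_keys = [_as_keys(l, r if not math.isinf(r) else 1e9)
                for l, r in intervals]

    # ordered and disjoint
    for (_lo, hi), (lo2, _hi2) in zip(int_keys, int_keys[1:]):
        assert hi < lo2
    for ilo, ihi in int_keys:
        for rlo, rhi in rec_keys:
            contained = rlo <= ilo and ihi <= rhi
            disjoint = ihi < rlo or rhi < ilo
            assert contained or disjoint
    for rlo, rhi in rec_keys:
        assert any(rlo <= ilo and ihi <= rhi for ilo, ihi in int_keys)
    # maximality: every candidate (left endpoint, right endpoint) interval
    # that respects all records overlaps one of the returned intervals
    lefts = sorted({k[0] for k in rec_keys})
    rights = sorted({k[1] for k in rec_keys})
    for lo in lefts:
        for hi in rights:
            if hi < lo:
                continue
            ok = all(
                (rlo <= lo and hi <= rhi) or hi < rlo or rhi < lo
                for rlo, rhi in rec_keys
            )
            inside_some = any(rlo <= lo and hi <= rhi for rlo, rhi in rec_keys)
            if ok and inside_some:
                assert any(not (ihi < lo or hi < ilo) for ilo, ihi in int_keys)


# ---------------------------------------------------------------------------
# NPMLE
# ---------------------------------------------------------------------------

def test_point_mass_curve():
    curve = s.npmle_fit([rec(5, 5)] * 10)
    assert curve.intervals == [(5, 5)]
    assert curve.masses[0] == pytest.approx(1.0, abs=1e-12)
    assert curve.survival(4.9) == 1.0
    assert curve.survival(5.0) == pytest.approx(0.0, abs=1e-12)


def test_single_record_gets_all_mass():
    curve = s.npmle_fit([rec(3, 6)])
    assert curve.intervals == [(3, 6)]
    assert curve.masses[0] == pytest.approx(1.0)


def test_masses_sum_to_one_and_survival_monotone():
    params = SurvivalGeneratorParams(median=20.0, n=120, study_end=45)
    records = s.gen_interval_survival(params, seed=8)
    curve = s.npmle_fit(records)
    assert curve.masses.sum() == pytest.approx(1.0, abs=1e-10)
    grid = np.linspace(0, 60, 121)
    vals = [curve.survival(t) for t in grid]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    lo, hi = zip(*(curve.survival_band(t) for t in grid))
    assert all(l <= h + 1e-12 for l, h in zip(lo, hi))


def test_em_loglikelihood_never_decreases():
    params = SurvivalGeneratorParams(median=25.0, n=80, study_end=60)
    records = s.gen_interval_survival(params, seed=3)
    curve = s.npmle_fit(records)
    path = curve.log_likelihood_path
    assert np.all(np.diff(path) >= -1e-9)


def test_npmle_equals_kaplan_meier_on_right_censored_data():
    """With exact deaths + right censoring the NPMLE is the product-limit
    estimator; compare pointwise against lifelines."""
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(12)
    death = rng.exponential(30.0, size=120)
    censor = rng.uniform(5.0, 70.0, size=120)
    obs = np.minimum(death, censor)
    event = death <= censor
    records = [
        rec(float(t), float(t)) if e else rec(float(t), INF)
        for t, e in zip(obs, event)
    ]
    curve = s.npmle_fit(records, tol=1e-12)
    km = KaplanMeierFitter().fit(obs, event)
    for t in np.unique(obs[event]):
        expected = float(km.survival_function_at_times(t).iloc[0])
        assert curve.survival(float(t)) == pytest.approx(expected, abs=1e-8)


def test_nonconvergence_reported():
    params = SurvivalGeneratorParams(median=25.0, n=150, study_end=60)
    records = s.gen_interval_survival(params, seed=5)
    with pytest.raises(NonConvergenceError):
        s.npmle_fit(records, tol=1e-12, max_iter=1)


# ---------------------------------------------------------------------------
# median
# ---------------------------------------------------------------------------

def test_median_of_point_mass_is_exact_with_zero_sd():
    records = [rec(5, 5)] * 20
    est = s.median_survival(records, n_boot=50, seed=1)
    assert est.median == 5.0
    assert est.sd == 0.0
    assert (est.ci_low, est.ci_high) == (5.0, 5.0)


def test_median_without_bootstrap():
    records = [rec(0, 3)] * 6 + [rec(3, 6)] * 6
    est = s.median_survival(records, n_boot=0)
    assert est.median == pytest.approx(1.5)  # midpoint convention
    assert est.sd is None


def test_median_unestimable_under_heavy_censoring():
    records = [rec(10, INF)] * 20 + [rec(2, 5)] * 2
    with pytest.raises(ValueError, match="unestimable"):
        s.median_survival(records, n_boot=0)


def test_median_recovery_from_gridded_exponential():
    params = SurvivalGeneratorParams(median=30.0, n=300, study_end=90)
    records = s.gen_interval_survival(params, seed=np.random.SeedSequence([4, 2]))
    est = s.median_survival(records, n_boot=200, seed=0)
    assert 24.0 <= est.median <= 36.0
    assert est.sd > 0
    assert est.ci_low <= est.median <= est.ci_high


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------

def test_identical_groups_give_null_result():
    records = s.gen_interval_survival(
        SurvivalGeneratorParams(median=20.0, n=40, study_end=60), seed=6
    )
    res = s.curve_difference_test(records, list(records), n_perm=49, seed=1)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_separated_groups_detected():
    """Longevity difference like wild-type (~30 d) vs test males (~53 d)."""
    a = s.gen_interval_survival(
        SurvivalGeneratorParams(median=30.0, n=100, study_end=90, group="wt"),
        seed=np.random.SeedSequence([9, 0]),
    )
    b = s.gen_interval_survival(
        SurvivalGeneratorParams(median=53.0, n=100, study_end=90, group="test"),
        seed=np.random.SeedSequence([9, 1]),
    )
    res = s.curve_difference_test(a, b, n_perm=99, seed=2)
    assert res.p_value == pytest.approx(1 / 100)


def test_permutation_test_is_seeded():
    a = s.gen_interval_survival(
        SurvivalGeneratorParams(median=25.0, n=30, study_end=60), seed=1
    )
    b = s.gen_interval_survival(
        SurvivalGeneratorParams(median=32.0, n=30, study_end=60), seed=2
    )
    r1 = s.curve_difference_test(a, b, n_perm=29, seed=7)
    r2 = s.curve_difference_test(a, b, n_perm=29, seed=7)
    assert r1.p_value == r2.p_value
    with pytest.raises(ValueError):
        s.curve_difference_test(a, b, n_perm=0)


def test_bonferroni_helper():
    out = s.adjust_pvalues([0.01, 0.4, 0.6])
    assert np.allclose(out, [0.03, 1.0, 1.0])


def test_csv_reader(tmp_path):
    path = tmp_path / "intervals.csv"
    path.write_text("group,left,right\nwt,0,3\nwt,3,6\nwt,9,inf\n")
    records = s.read_interval_csv(path)
    assert len(records) == 3
    assert math.isinf(records[-1].right)
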