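"""Calibration, daily update, releases and full runs of the population model."""

import math
from dataclasses import replace

import numpy as np
import pytest

import sitsim as s
from sitsim.cubes import FEMALE, MALE, PG, WT
from sitsim.dynamics import CalibrationError, _empty_state


def total_individuals(state):
    juv = sum(
        arr.sum()
        for stage in (state.eggs, state.larvae, state.pupae)
        for arr in stage.values()
    )
    return (
        juv
        + state.total_adult_males()
        + state.adult_females()
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_mu_aqua_solves_growth_rate_identity():
    lh, _ = s.calibrate_equilibrium(s.LifeHistory(rm=8.2))
    lhs = (lh.beta / (2 * lh.mu_adult)) * (1 - lh.mu_aqua) ** lh.juvenile_days
    assert math.isclose(lhs, lh.rm, rel_tol=1e-12)


def test_mu_aqua_boundary_case_zero():
    """When lifetime egg output exactly equals Rm, juveniles need no
    extra density-independent mortality."""
    lh = s.LifeHistory(beta=2 * 1.1 * 0.123, rm=1.1, n_female_eq=100.0)
    calibrated, _ = s.calibrate_equilibrium(lh)
    assert abs(calibrated.mu_aqua) < 1e-12


def test_calibration_errors():
    with pytest.raises(CalibrationError):
        s.calibrate_equilibrium(s.LifeHistory(n_female_eq=0))
    with pytest.raises(CalibrationError):
        s.calibrate_equilibrium(s.LifeHistory(rm=0.9))
    with pytest.raises(CalibrationError):
        # growth rate unattainable: would need negative juvenile mortality
        s.calibrate_equilibrium(s.LifeHistory(beta=1.0, rm=8.2))


@pytest.mark.parametrize("rm", [1.1, 8.2])
def test_equilibrium_is_deterministic_fixed_point(rm, wild_cube):
    """A 365-day deterministic run from the calibrated state is flat."""
    lh, state = s.calibrate_equilibrium(
        s.LifeHistory(rm=rm, n_female_eq=10_000.0), wild_cube
    )
    f0 = state.adult_females()
    assert math.isclose(f0, 10_000.0, rel_tol=1e-9)
    traj = s.run(lh, wild_cube, horizon=365, mode="deterministic",
                 initial_state=state)
    females = traj.total_adult_females()
    assert np.max(np.abs(females - f0) / f0) < 1e-9


def test_alpha_increases_equilibrium_larval_capacity():
    """Weaker density dependence (larger alpha) at fixed Rm means the
    calibrated equilibrium supports more larvae per female."""
    lh1, st1 = s.calibrate_equilibrium(s.LifeHistory(rm=2.0, n_female_eq=1000))
    lh2, st2 = s.calibrate_equilibrium(s.LifeHistory(rm=8.2, n_female_eq=1000))
    # alpha is an output here; check the stationary larval load it implies
    assert st1.total_larvae() != st2.total_larvae()
    for lh, st in ((lh1, st1), (lh2, st2)):
        # direct check: at equilibrium the daily density factor equals Rm^(-1/T_L)
        dd = (lh.alpha / (lh.alpha + st.total_larvae())) ** (1 / lh.t_larva)
        assert math.isclose(dd, lh.rm ** (-1 / lh.t_larva), rel_tol=1e-12)


# ---------------------------------------------------------------------------
# step
# ---------------------------------------------------------------------------

def test_no_fecundity_gives_geometric_adult_decay(wild_cube):
    lh, state = s.calibrate_equilibrium(
        s.LifeHistory(n_female_eq=1000.0), wild_cube
    )
    barren = replace(lh, beta=0.0)
    x = state
    for _ in range(10):
        x = s.step(x, barren, wild_cube)
    # adults decay at (1 - mu_adult) apart from pipeline emergence; after
    # T_E+T_L+T_P days the juvenile stages must be empty
    for _ in range(lh.juvenile_days - 10):
        x = s.step(x, barren, wild_cube)
    juveniles = sum(
        arr.sum()
        for stage in (x.eggs, x.larvae, x.pupae)
        for arr in stage.values()
    )
    assert juveniles == 0.0
    # from an empty pipeline, decay is exactly geometric
    f0 = x.adult_females()
    for _ in range(5):
        x = s.step(x, barren, wild_cube)
    assert math.isclose(x.adult_females(), f0 * (1 - lh.mu_adult) ** 5,
                        rel_tol=1e-12)


def test_stochastic_step_is_reproducible(calibrated_small, wild_cube):
    lh, state = calibrated_small
    st = state.round_to_integers()
    a = s.step(st, lh, wild_cube, mode="stochastic",
               rng=np.random.default_rng(42))
    b = s.step(st, lh, wild_cube, mode="stochastic",
               rng=np.random.default_rng(42))
    assert a.adult_males == b.adult_males
    assert a.mated_females == b.mated_females
    for cls in a.eggs:
        assert np.array_equal(a.eggs[cls], b.eggs[cls])
        assert np.array_equal(a.larvae[cls], b.larvae[cls])
        assert np.array_equal(a.pupae[cls], b.pupae[cls])


@pytest.mark.parametrize("mode", ["deterministic", "stochastic"])
def test_step_conserves_individuals(mode, calibrated_small, wild_cube):
    """Individuals leave a class only by death, programmed lethality or
    promotion; no class gains from nowhere."""
    lh, state = calibrated_small
    if mode == "stochastic":
        state = state.round_to_integers()
    rng = np.random.default_rng(7)
    x = state
    for _ in range(5):
        before = total_individuals(x)
        x, audit = s.step(x, lh, wild_cube, mode=mode, rng=rng, audit=True)
        after = total_individuals(x)
        balance = (
            before
            + audit.eggs_laid
            - audit.deaths_adult
            - audit.deaths_juvenile
            - audit.culled
        )
        assert math.isclose(after, balance, rel_tol=1e-9, abs_tol=1e-6)


def test_mated_females_never_remate():
    """The mate-genotype marginal of mated females changes only through
    mortality and emergence inflow, never by switching mates."""
    cube = s.build_cube("pgsit")
    lh, state = s.calibrate_equilibrium(
        s.default_life_history(n_female_eq=500.0), cube
    )
    # big sterile male cohort makes new matings overwhelmingly pgSIT
    state.adult_males[PG] = 50_000.0
    surv = 1 - lh.mu_adult
    x = state
    for _ in range(5):
        prev = dict(x.mated_females)
        x = s.step(x, lh, cube)
        for key, n in prev.items():
            inflow_free = n * surv
            # wild-mate classes only shrink by mortality plus tiny wild inflow
            assert x.mated_females.get(key, 0.0) >= inflow_free - 1e-9


def test_females_without_males_stay_unmated_and_mate_later(wild_cube):
    lh, _ = s.calibrate_equilibrium(
        s.LifeHistory(n_female_eq=100.0), wild_cube
    )
    state = _empty_state(lh, wild_cube)
    state.pupae[(WT, FEMALE)][-1] = 100.0
    out = s.step(state, lh, wild_cube)
    assert out.mated_females == {}
    assert out.unmated_females[WT] > 0
    # introduce males: the unmated pool mates on the next day
    out.adult_males[WT] = 50.0
    out2 = s.step(out, lh, wild_cube)
    assert out2.unmated_females == {}
    assert out2.mated_females[(WT, WT)] > 0


def test_zero_competitiveness_males_never_mate():
    cube = s.build_cube("pgsit", c=0.0)
    lh, state = s.calibrate_equilibrium(
        s.default_life_history(n_female_eq=200.0), cube
    )
    state.adult_males[PG] = 1e6
    x = state
    for _ in range(20):
        x = s.step(x, lh, cube)
    assert all(mg != PG for (_fg, mg) in x.mated_females)


# ---------------------------------------------------------------------------
# releases
# ---------------------------------------------------------------------------

def test_adult_release_adds_exact_count():
    cube = s.build_cube("ridl")
    lh, state = s.calibrate_equilibrium(
        s.default_life_history(n_female_eq=100.0), cube
    )
    ev = s.ReleaseEvent(day=1, genotype="RR", stage="adult_male", size=200_000)
    out = s.apply_release(state, ev, cube)
    assert out.adult_males["RR"] == 200_000.0


def test_egg_release_splits_sexes_equally():
    cube = s.build_cube("pgsit")
    lh, state = s.calibrate_equilibrium(
        s.default_life_history(n_female_eq=100.0), cube
    )
    ev = s.ReleaseEvent(day=1, genotype=PG, stage="egg", size=1000)
    out = s.apply_release(state, ev, cube)
    assert out.eggs[(PG, FEMALE)][0] == 500.0
    assert out.eggs[(PG, MALE)][0] == 500.0


def test_release_stage_mismatch_rejected():
    cube = s.build_cube("pgsit")
    lh, state = s.calibrate_equilibrium(
        s.default_life_history(n_female_eq=100.0), cube
    )
    ev = s.ReleaseEvent(day=1, genotype=PG, stage="adult_male", size=10)
    with pytest.raises(ValueError, match="release stage"):
        s.apply_release(state, ev, cube)


def test_ratio_release_sizing():
    sched = s.ReleaseSchedule.periodic(
        ratio=10, reference_adults=20_000, stage="adult_male", genotype="RR",
        n_releases=3,
    )
    assert [e.size for e in sched.events] == [200_000.0] * 3
    assert [e.day for e in sched.events] == [1, 8, 15]


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_same_seed_same_trajectory():
    cfg = s.gen_scenario_fixture("fig4d_scaled")
    lh = cfg.make_life_history()
    cube = cfg.make_cube()
    lh, eq = s.calibrate_equilibrium(lh, cube)
    sched = cfg.make_schedule(cube, lh)
    a = s.run(lh, cube, sched, horizon=60, mode="stochastic", seed=11,
              initial_state=eq)
    b = s.run(lh, cube, sched, horizon=60, mode="stochastic", seed=11,
              initial_state=eq)
    assert np.array_equal(a.total_adult_females(), b.total_adult_females())
    assert a.elimination_day == b.elimination_day


def test_bigger_releases_never_leave_more_females_deterministic():
    """Deterministic day-180 wild females are non-increasing in release size."""
    day180 = []
    for ratio in (0.0, 50.0, 200.0):
        cfg = s.ScenarioConfig(
            system="pgsit", ratio=ratio, mode="deterministic",
            life_history={"n_female_eq": 500.0}, horizon=180,
        )
        lh = cfg.make_life_history()
        cube = cfg.make_cube()
        lh, eq = s.calibrate_equilibrium(lh, cube)
        sched = cfg.make_schedule(cube, lh)
        traj = s.run(lh, cube, sched, horizon=180, mode="deterministic",
                     initial_state=eq)
        day180.append(traj.total_adult_females()[180])
    assert day180[0] >= day180[1] >= day180[2]
    assert day180[2] < 0.5 * day180[0]


def test_run_rejects_bad_horizon(calibrated_small, wild_cube):
    lh, eq = calibrated_small
    with pytest.raises(ValueError):
        s.run(lh, wild_cube, horizon=0, initial_state=eq)
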