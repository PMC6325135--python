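"""Daily-time-step, genotype-explicit mosquito population dynamics.

The model tracks eggs, larvae and pupae by age-within-stage and by
(genotype, sex) class, adult males by genotype, and adult females by
(own genotype, mate genotype) — females mate exactly once upon emergence
and retain their mate's genotype for life. Generations overlap; one call
to :func:`step` advances the population by one day:

1. oviposition — every mated-female class lays ``beta`` eggs per female
   per day, reduced by the cross's viable-egg fraction and distributed
   over offspring classes by the inheritance cube;
2. mortality — adults die with probability ``omega * mu_adult``; all
   juvenile stages share the density-independent daily mortality
   ``mu_aqua``; larvae additionally survive with probability
   ``(alpha / (alpha + L))**(1/T_L)`` where ``L`` is the total larval
   count (a Beverton–Holt-type larval competition term);
3. stage progression — final-age eggs hatch, final-age larvae pupate
   (classes flagged to die at larva exit are removed here, after a full
   larval life of resource consumption), final-age pupae emerge (pupal-
   exit lethality removed here);
4. mating — each newly emerged female samples a mate genotype with
   probability proportional to competitiveness times male abundance;
   females emerging with no males present stay in an unmated pool and
   retry daily.

In stochastic mode all transitions are binomial/Poisson/multinomial
draws on integer counts; the deterministic mode iterates the mean field
on real-valued counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .cubes import (
    DS_EGG,
    DS_LARVA_EXIT,
    DS_NONE,
    DS_PUPA_EXIT,
    FEMALE,
    MALE,
    RELEASE_ADULT_MALE,
    RELEASE_EGG,
    SEXES,
    WT,
    InterventionCube,
    build_cube,
)

Class = tuple[str, str]

DETERMINISTIC = "deterministic"
STOCHASTIC = "stochastic"
MODES = (DETERMINISTIC, STOCHASTIC)


class CalibrationError(ValueError):
    """Raised when life-history parameters admit no valid calibration."""


@dataclass
class LifeHistory:
    """Life-history and density-dependence parameters.

    Parameters
    ----------
    beta
        Eggs laid per adult female per day.
    mu_adult
        Daily adult mortality probability.
    t_egg, t_larva, t_pupa
        Stage durations in days.
    rm
        Per-generation population growth rate in the absence of
        density-dependent mortality; must exceed 1 for a viable
        population.
    n_female_eq
        Target number of adult females at equilibrium.
    mu_aqua
        Daily density-independent juvenile mortality, identical across
        egg/larva/pupa; filled in by :func:`calibrate_equilibrium`.
    alpha
        Larval-competition scale (larval count at which the extra
        density-dependent mortality halves recruitment relative to its
        maximum); filled in by :func:`calibrate_equilibrium`.
    """

    beta: float = 20.0
    mu_adult: float = 0.123
    t_egg: int = 5
    t_larva: int = 6
    t_pupa: int = 4
    rm: float = 8.2
    n_female_eq: float = 10_000.0
    mu_aqua: float | None = None
    alpha: float | None = None

    @property
    def juvenile_days(self) -> int:
        return self.t_egg + self.t_larva + self.t_pupa

    @property
    def calibrated(self) -> bool:
        return self.mu_aqua is not None and self.alpha is not None


@dataclass
class PopulationState:
    """Age-structured counts per stage x (genotype, sex) class.

    Juvenile arrays are indexed ``[age - 1]`` with age running 1..T for
    the stage. ``mated_females`` is keyed by (own genotype, mate
    genotype); ``unmated_females`` holds newly emerged females that
    found no males and retry mating daily.
    """

    eggs: dict[Class, np.ndarray]
    larvae: dict[Class, np.ndarray]
    pupae: dict[Class, np.ndarray]
    adult_males: dict[str, float]
    mated_females: dict[tuple[str, str], float]
    unmated_females: dict[str, float]
    day: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(
            eggs={k: v.copy() for k, v in self.eggs.items()},
            larvae={k: v.copy() for k, v in self.larvae.items()},
            pupae={k: v.copy() for k, v in self.pupae.items()},
            adult_males=dict(self.adult_males),
            mated_females=dict(self.mated_females),
            unmated_females=dict(self.unmated_females),
            day=self.day,
        )

    # -- totals --------------------------------------------------------------
    def total_larvae(self) -> float:
        return float(sum(a.sum() for a in self.larvae.values()))

    def adult_females(self, genotype: str | None = None) -> float:
        mated = sum(
            n for (fg, _mg), n in self.mated_females.items()
            if genotype is None or fg == genotype
        )
        unmated = sum(
            n for g, n in self.unmated_females.items()
            if genotype is None or g == genotype
        )
        return float(mated + unmated)

    def total_adult_males(self) -> float:
        return float(sum(self.adult_males.values()))

    def genotype_count(self, genotype: str) -> float:
        """All individuals of one genotype across every stage and sex."""
        total = 0.0
        for stage in (self.eggs, self.larvae, self.pupae):
            for (g, _s), arr in stage.items():
                if g == genotype:
                    total += arr.sum()
        total += self.adult_males.get(genotype, 0.0)
        total += self.unmated_females.get(genotype, 0.0)
        total += sum(n for (fg, _mg), n in self.mated_females.items() if fg == genotype)
        return float(total)

    def round_to_integers(self) -> "PopulationState":
        """Integerized copy used to seed stochastic realizations."""
        out = self.copy()
        for stage in (out.eggs, out.larvae, out.pupae):
            for k in stage:
                stage[k] = np.round(stage[k]).astype(np.int64)
        out.adult_males = {g: float(round(n)) for g, n in out.adult_males.items()}
        out.mated_females = {k: float(round(n)) for k, n in out.mated_females.items()}
        out.unmated_females = {g: float(round(n)) for g, n in out.unmated_females.items()}
        return out


@dataclass(frozen=True)
class ReleaseEvent:
    day: int
    genotype: str
    stage: str  # "egg" or "adult_male"
    size: float

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("release size must be >= 0")


@dataclass
class ReleaseSchedule:
    """Timed release events, usually weekly over the intervention window."""

    events: list[ReleaseEvent] = field(default_factory=list)

    def on_day(self, day: int) -> list[ReleaseEvent]:
        return [e for e in self.events if e.day == day]

    @classmethod
    def periodic(
        cls,
        ratio: float,
        reference_adults: float,
        stage: str,
        genotype: str,
        period: int = 7,
        n_releases: int = 26,
        first_day: int = 1,
    ) -> "ReleaseSchedule":
        """Build releases sized as ``ratio`` per reference wild adult.

        ``reference_adults`` is fixed once (by default the pre-intervention
        equilibrium adult count, males plus females), matching release
        ratios that are quoted 'per wild adult' and set before the
        campaign starts.
        """
        size = ratio * reference_adults
        events = [
            ReleaseEvent(day=first_day + k * period, genotype=genotype,
                         stage=stage, size=size)
            for k in range(n_releases)
        ]
        return cls(events=events)


@dataclass
class StepAudit:
    """Per-step accounting used by the conservation checks."""

    eggs_laid: float = 0.0
    deaths_adult: float = 0.0
    deaths_juvenile: float = 0.0
    culled: float = 0.0  # programmed lethality at stage exits
    emerged_females: float = 0.0
    emerged_males: float = 0.0


@dataclass
class Trajectory:
    """Per-day records of one simulation run."""

    days: np.ndarray
    adult_females: dict[str, np.ndarray]   # by own genotype
    adult_males: dict[str, np.ndarray]     # by genotype
    larvae: dict[str, np.ndarray]          # by genotype
    elimination_day: int | None = None

    def total_adult_females(self) -> np.ndarray:
        return np.sum(list(self.adult_females.values()), axis=0)

    def total_adult_males(self) -> np.ndarray:
        return np.sum(list(self.adult_males.values()), axis=0)

    def total_larvae(self) -> np.ndarray:
        return np.sum(list(self.larvae.values()), axis=0)

    def to_frame(self):
        """Tidy long-format table (day, quantity, genotype, count)."""
        import pandas as pd

        rows = []
        for name, table in (
            ("adult_females", self.adult_females),
            ("adult_males", self.adult_males),
            ("larvae", self.larvae),
        ):
            for g, arr in table.items():
                rows.append(pd.DataFrame(
                    {"day": self.days, "quantity": name, "genotype": g, "count": arr}
                ))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_equilibrium(
    params: LifeHistory, cube: InterventionCube | None = None
) -> tuple[LifeHistory, PopulationState]:
    """Fill ``mu_aqua`` and ``alpha`` and return the wild equilibrium state.

    ``mu_aqua`` solves ``(beta / (2 mu_adult)) (1 - mu_aqua)^T = Rm`` with
    ``T`` the total juvenile duration, so that ``Rm`` is the per-generation
    growth rate absent density dependence. ``alpha`` is then fixed in
    closed form so the daily larval density factor at the stationary
    larval population equals ``Rm**(-1)`` per larval stage — which makes
    the returned state an exact fixed point of the deterministic
    :func:`step`.
    """
    if params.n_female_eq <= 0:
        raise CalibrationError("n_female_eq must be > 0")
    if params.rm <= 1.0:
        raise CalibrationError("rm must exceed 1 for a viable population")
    if not 0 < params.mu_adult < 1:
        raise CalibrationError("mu_adult must be in (0, 1)")
    if params.beta <= 0:
        raise CalibrationError("beta must be > 0")
    x = 2.0 * params.rm * params.mu_adult / params.beta
    if not 0.0 < x <= 1.0:
        raise CalibrationError(
            "no juvenile mortality in (0, 1) is consistent with these "
            f"parameters (2*Rm*mu_adult/beta = {x:.4g} not in (0, 1])"
        )
    t_total = params.juvenile_days
    mu_aqua = 1.0 - x ** (1.0 / t_total)

    s = 1.0 - mu_aqua
    # daily density-dependent larval survival factor at equilibrium
    d_eq = params.rm ** (-1.0 / params.t_larva)
    egg_input = params.beta * params.n_female_eq          # eggs laid per day
    hatch = egg_input * s ** params.t_egg                 # larvae entering per day
    l_eq = hatch * sum((s * d_eq) ** k for k in range(params.t_larva))
    alpha = l_eq * (1.0 / params.rm) / (1.0 - 1.0 / params.rm)

    calibrated = replace(params, mu_aqua=mu_aqua, alpha=alpha)

    cube = cube if cube is not None else build_cube("wild")
    state = _wild_equilibrium_state(calibrated, cube, egg_input, hatch, s, d_eq)
    # postcondition: target female count reproduced
    assert abs(state.adult_females() - params.n_female_eq) <= 1e-3 * params.n_female_eq
    return calibrated, state


def _empty_state(params: LifeHistory, cube: InterventionCube) -> PopulationState:
    classes = [(g, s) for g in cube.genotypes for s in SEXES]
    return PopulationState(
        eggs={c: np.zeros(params.t_egg) for c in classes},
        larvae={c: np.zeros(params.t_larva) for c in classes},
        pupae={c: np.zeros(params.t_pupa) for c in classes},
        adult_males={g: 0.0 for g in cube.genotypes},
        mated_females={},
        unmated_females={},
        day=0,
    )


def _wild_equilibrium_state(params, cube, egg_input, hatch, s, d_eq):
    state = _empty_state(params, cube)
    ages_e = np.arange(params.t_egg)
    ages_l = np.arange(params.t_larva)
    ages_p = np.arange(params.t_pupa)
    pupal_in = hatch * (s * d_eq) ** params.t_larva
    for sex in SEXES:
        state.eggs[(WT, sex)] = 0.5 * egg_input * s ** ages_e
        state.larvae[(WT, sex)] = 0.5 * hatch * (s * d_eq) ** ages_l
        state.pupae[(WT, sex)] = 0.5 * pupal_in * s ** ages_p
    state.adult_males[WT] = params.n_female_eq
    state.mated_females[(WT, WT)] = params.n_female_eq
    return state


# ---------------------------------------------------------------------------
# one-day update
# ---------------------------------------------------------------------------

def _surv_det(n, p):
    return n * p


def step(
    state: PopulationState,
    params: LifeHistory,
    cube: InterventionCube,
    mode: str = DETERMINISTIC,
    rng: np.random.Generator | None = None,
    audit: bool = False,
):
    """Advance the population by one day; returns the new state.

    With ``audit=True`` returns ``(state, StepAudit)`` with the day's
    births/deaths accounting, used to verify that no class gains or
    loses individuals except through the modeled events.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    det = mode == DETERMINISTIC
    if not det and rng is None:
        raise ValueError("stochastic mode requires an rng")
    if not params.calibrated:
        raise ValueError("params must be calibrated (run calibrate_equilibrium)")

    rep = StepAudit()
    s_aq = 1.0 - params.mu_aqua
    l_total = state.total_larvae()
    dd = (params.alpha / (params.alpha + l_total)) ** (1.0 / params.t_larva) \
        if l_total > 0 else 1.0

    def binom(n, p):
        if det:
            return n * p
        return rng.binomial(np.asarray(n, dtype=np.int64), p)

    # --- 1. oviposition (start-of-day mated females) -----------------------
    new_eggs: dict[Class, float] = {}
    for (fg, mg), count in state.mated_females.items():
        if count <= 0:
            continue
        od = cube.offspring(fg, mg)
        lam = params.beta * count * od.viable_egg_fraction
        if lam <= 0 or not od.entries:
            continue
        classes = list(od.entries.keys())
        probs = np.array([od.entries[c] for c in classes])
        if det:
            for c, p in zip(classes, probs):
                new_eggs[c] = new_eggs.get(c, 0.0) + lam * p
        else:
            total = rng.poisson(lam)
            if total > 0:
                draws = rng.multinomial(total, probs / probs.sum())
                for c, n in zip(classes, draws):
                    if n:
                        new_eggs[c] = new_eggs.get(c, 0.0) + float(n)
    rep.eggs_laid = float(sum(new_eggs.values()))

    # --- 2. adult survival --------------------------------------------------
    adult_males = {}
    for g, n in state.adult_males.items():
        p_surv = max(0.0, 1.0 - cube.omega(g) * params.mu_adult)
        survived = float(binom(n, p_surv))
        rep.deaths_adult += n - survived
        adult_males[g] = survived
    mated_females = {}
    for (fg, mg), n in state.mated_females.items():
        p_surv = max(0.0, 1.0 - cube.omega(fg) * params.mu_adult)
        survived = float(binom(n, p_surv))
        rep.deaths_adult += n - survived
        if survived > 0:
            mated_females[(fg, mg)] = survived
    unmated = {}
    for g, n in state.unmated_females.items():
        p_surv = max(0.0, 1.0 - cube.omega(g) * params.mu_adult)
        survived = float(binom(n, p_surv))
        rep.deaths_adult += n - survived
        if survived > 0:
            unmated[g] = survived

    # --- 3. juvenile survival and stage progression ------------------------
    eggs_next: dict[Class, np.ndarray] = {}
    larvae_next: dict[Class, np.ndarray] = {}
    pupae_next: dict[Class, np.ndarray] = {}
    emerged_f: dict[str, float] = {}

    dtype0 = np.float64 if det else np.int64
    all_classes = set(state.eggs) | set(new_eggs)
    zeros = {
        "egg": np.zeros(params.t_egg, dtype=dtype0),
        "larva": np.zeros(params.t_larva, dtype=dtype0),
        "pupa": np.zeros(params.t_pupa, dtype=dtype0),
    }
    for cls in sorted(all_classes):
        g, sex = cls
        e_surv = binom(state.eggs.get(cls, zeros["egg"]), s_aq)
        l_surv = binom(state.larvae.get(cls, zeros["larva"]), s_aq * dd)
        p_surv = binom(state.pupae.get(cls, zeros["pupa"]), s_aq)
        rep.deaths_juvenile += float(
            state.eggs.get(cls, zeros["egg"]).sum() - e_surv.sum()
            + state.larvae.get(cls, zeros["larva"]).sum() - l_surv.sum()
            + state.pupae.get(cls, zeros["pupa"]).sum() - p_surv.sum()
        )
        death = cube.death_stage_of(g, sex)

        hatching = float(e_surv[-1])
        if death == DS_EGG and hatching > 0:
            rep.culled += hatching
            hatching = 0.0
        pupating = float(l_surv[-1])
        if death == DS_LARVA_EXIT and pupating > 0:
            rep.culled += pupating
            pupating = 0.0
        emerging = float(p_surv[-1])
        if death == DS_PUPA_EXIT and emerging > 0:
            rep.culled += emerging
            emerging = 0.0

        dtype = np.float64 if det else np.int64
        eggs_next[cls] = np.concatenate(
            ([new_eggs.get(cls, 0.0)], e_surv[:-1])
        ).astype(dtype)
        larvae_next[cls] = np.concatenate(([hatching], l_surv[:-1])).astype(dtype)
        pupae_next[cls] = np.concatenate(([pupating], p_surv[:-1])).astype(dtype)

        if emerging > 0:
            if sex == MALE:
                adult_males[g] = adult_males.get(g, 0.0) + emerging
                rep.emerged_males += emerging
            else:
                emerged_f[g] = emerged_f.get(g, 0.0) + emerging
                rep.emerged_females += emerging

    # --- 4. mating of newly emerged (and previously unmated) females -------
    to_mate: dict[str, float] = dict(emerged_f)
    for g, n in unmated.items():
        to_mate[g] = to_mate.get(g, 0.0) + n
    unmated_next: dict[str, float] = {}

    male_genos = [g for g, n in adult_males.items() if n > 0]
    weights = np.array([cube.c(g) * adult_males[g] for g in male_genos])
    w_total = float(weights.sum())
    if w_total > 0:
        probs = weights / w_total
        for fg, n in to_mate.items():
            if n <= 0:
                continue
            if det:
                for mg, p in zip(male_genos, probs):
                    if p > 0:
                        key = (fg, mg)
                        mated_females[key] = mated_females.get(key, 0.0) + n * p
            else:
                draws = rng.multinomial(int(n), probs)
                for mg, k in zip(male_genos, draws):
                    if k:
                        key = (fg, mg)
                        mated_females[key] = mated_females.get(key, 0.0) + float(k)
    else:
        unmated_next = {g: n for g, n in to_mate.items() if n > 0}

    new_state = PopulationState(
        eggs=eggs_next,
        larvae=larvae_next,
        pupae=pupae_next,
        adult_males=adult_males,
        mated_females=mated_females,
        unmated_females=unmated_next,
        day=state.day + 1,
    )
    if audit:
        return new_state, rep
    return new_state


# ---------------------------------------------------------------------------
# releases
# ---------------------------------------------------------------------------

def apply_release(
    state: PopulationState, event: ReleaseEvent, cube: InterventionCube
) -> PopulationState:
    """Add released individuals to the state (in a copy).

    Adult-male releases add to the adult male pool; egg releases add a
    1:1 sex-split cohort at egg age 1, with the cube's death-stage rules
    attached through the class labels.
    """
    if event.genotype not in cube.genotypes:
        raise ValueError(f"release genotype {event.genotype!r} not in cube")
    if event.stage != cube.release_stage:
        raise ValueError(
            f"release stage {event.stage!r} does not match cube "
            f"release stage {cube.release_stage!r}"
        )
    out = state.copy()
    if event.stage == RELEASE_ADULT_MALE:
        out.adult_males[event.genotype] = (
            out.adult_males.get(event.genotype, 0.0) + event.size
        )
    elif event.stage == RELEASE_EGG:
        half = event.size / 2.0
        if out.eggs[(event.genotype, FEMALE)].dtype == np.int64:
            lo, hi = math.floor(half), math.ceil(half)
            out.eggs[(event.genotype, FEMALE)][0] += lo
            out.eggs[(event.genotype, MALE)][0] += hi
        else:
            out.eggs[(event.genotype, FEMALE)][0] += half
            out.eggs[(event.genotype, MALE)][0] += half
    else:
        raise ValueError(f"unknown release stage {event.stage!r}")
    return out


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def reproducing_count(state: PopulationState, cube: InterventionCube) -> float:
    """Individuals that can still contribute to future reproduction.

    Counts every life stage of the wild type and of any genotype with
    fertile, adulthood-reaching males (e.g. fsRIDL carriers). Released
    sterile or dead-end classes do not block elimination.
    """
    return sum(state.genotype_count(g) for g in cube.reproductive_genotypes())


def run(
    params: LifeHistory,
    cube: InterventionCube,
    schedule: ReleaseSchedule | None = None,
    horizon: int = 365,
    mode: str = DETERMINISTIC,
    seed: int | np.random.SeedSequence | None = None,
    initial_state: PopulationState | None = None,
) -> Trajectory:
    """Simulate ``horizon`` days from equilibrium and record daily totals.

    ``elimination_day`` is set (stochastic mode only) on the first day
    the reproducing population hits zero.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not params.calibrated or initial_state is None:
        params, eq_state = calibrate_equilibrium(params, cube)
        state = eq_state if initial_state is None else initial_state
    else:
        state = initial_state
    det = mode == DETERMINISTIC
    rng = None
    if not det:
        rng = np.random.default_rng(seed)
        state = state.round_to_integers()
    else:
        state = state.copy()

    genos = cube.genotypes
    females = {g: np.zeros(horizon + 1) for g in genos}
    males = {g: np.zeros(horizon + 1) for g in genos}
    larvae = {g: np.zeros(horizon + 1) for g in genos}

    def record(day_idx: int) -> None:
        for g in genos:
            females[g][day_idx] = state.adult_females(g)
            males[g][day_idx] = state.adult_males.get(g, 0.0)
            larvae[g][day_idx] = sum(
                state.larvae[(g, s)].sum() for s in SEXES if (g, s) in state.larvae
            )

    record(0)
    elimination_day = None
    schedule = schedule or ReleaseSchedule()
    for day in range(1, horizon + 1):
        for event in schedule.on_day(day):
            state = apply_release(state, event, cube)
        state = step(state, params, cube, mode=mode, rng=rng)
        record(day)
        if not det and elimination_day is None and reproducing_count(state, cube) == 0:
            elimination_day = day
    return Trajectory(
        days=np.arange(horizon + 1),
        adult_females=females,
        adult_males=males,
        larvae=larvae,
        elimination_day=elimination_day,
    )
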