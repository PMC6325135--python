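"""Synthetic data generators matching the assay and study designs.

Every analysis in the package can be exercised end to end without any
external data: the competition-assay generator reproduces the cage
design (replicated cages of ten females with fixed male compositions,
Poisson egg counts, binomial hatch), the survival generator reproduces
interval censoring from periodic vial inspections (deaths recorded
every third day, right-censored at study end), and the scenario
fixtures provide fully specified, seeded simulation configurations.
All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .competition import ASSAY_COLUMNS, expected_hatch
from .config import ScenarioConfig
from .survival import IntervalRecord


@dataclass
class AssayGeneratorParams:
    """Design of a synthetic mate-competition assay.

    Mirrors the experimental layout: ``n_replicates`` mixed cages with
    ``n_wt`` wild plus ``n_test`` test males, the same number of control
    cages with ``control_n_wt`` wild males only, ``n_females`` per cage.
    Each female mates once (test male with probability
    ``c * n_test / (n_wt + c * n_test)``), lays a Poisson number of eggs,
    and eggs hatch binomially at ``h0`` (wild-sired) or ``h_sterile``.
    ``overdispersion`` (a beta-binomial precision, smaller = noisier)
    adds extra-binomial cage-level variation when set.
    """

    c_true: float = 0.78
    h0: float = 0.851
    h_sterile: float = 0.0
    n_replicates: int = 5
    n_females: int = 10
    n_wt: int = 1
    n_test: int = 1
    control_n_wt: int = 2
    eggs_per_female: float = 20.0
    overdispersion: float | None = None


@dataclass
class SurvivalGeneratorParams:
    """Design of a synthetic interval-censored longevity study.

    True death times are drawn from an exponential (parameterized by its
    median) or Weibull distribution; deaths are only recorded at
    inspections every ``inspection_period`` days, and animals alive at
    ``study_end`` are right-censored.
    """

    distribution: str = "exponential"
    median: float = 30.0
    shape: float = 1.0            # Weibull shape (1 = exponential)
    inspection_period: int = 3
    study_end: float = 90.0
    n: int = 60
    group: str = "group"

    def __post_init__(self) -> None:
        if self.distribution not in ("exponential", "weibull"):
            raise ValueError("distribution must be 'exponential' or 'weibull'")
        if self.inspection_period < 1:
            raise ValueError("inspection_period must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.median < 0:
            raise ValueError("median must be >= 0")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")


def _hatch_prob(rng, h: float, kappa: float | None) -> float:
    """Cage-level hatch probability, beta-distributed if overdispersed."""
    if kappa is None or h in (0.0, 1.0):
        return h
    return float(rng.beta(h * kappa, (1.0 - h) * kappa))


def gen_competition_assay(
    params: AssayGeneratorParams, seed: int | np.random.SeedSequence | None = None
) -> pd.DataFrame:
    """Simulate one assay; returns a table with both mixed and control cages."""
    if not 0 <= params.h0 <= 1 or not 0 <= params.h_sterile <= 1:
        raise ValueError("hatch probabilities must be in [0, 1]")
    if params.c_true < 0:
        raise ValueError("c_true must be >= 0")
    rng = np.random.default_rng(seed)
    p_test = (
        params.c_true * params.n_test
        / (params.n_wt + params.c_true * params.n_test)
    )
    rows = []
    rep = 0
    for _ in range(params.n_replicates):  # mixed cages
        rep += 1
        n_test_mated = rng.binomial(params.n_females, p_test)
        laid = hatched = 0
        for mated_test in ([True] * n_test_mated
                           + [False] * (params.n_females - n_test_mated)):
            eggs = rng.poisson(params.eggs_per_female)
            h = params.h_sterile if mated_test else params.h0
            h = _hatch_prob(rng, h, params.overdispersion)
            laid += eggs
            hatched += rng.binomial(eggs, h)
        rows.append((rep, params.n_wt, params.n_test, params.n_females,
                     laid, hatched))
    for _ in range(params.n_replicates):  # control cages
        rep += 1
        laid = hatched = 0
        for _f in range(params.n_females):
            eggs = rng.poisson(params.eggs_per_female)
            h = _hatch_prob(rng, params.h0, params.overdispersion)
            laid += eggs
            hatched += rng.binomial(eggs, h)
        rows.append((rep, params.control_n_wt, 0, params.n_females,
                     laid, hatched))
    return pd.DataFrame(rows, columns=list(ASSAY_COLUMNS))


def expected_mixed_hatch(params: AssayGeneratorParams) -> float:
    """Closed-form expected hatch rate of the mixed cages."""
    return expected_hatch(
        params.c_true, params.h0, params.n_wt, params.n_test, params.h_sterile
    )


def gen_interval_survival(
    params: SurvivalGeneratorParams,
    seed: int | np.random.SeedSequence | None = None,
) -> list[IntervalRecord]:
    """Simulate interval-censored death records from periodic inspections.

    Death in inspection window ``(k*p, (k+1)*p]`` is recorded as exactly
    that interval; survival past ``study_end`` yields a right-censored
    record ``(study_end, inf)``. A zero-hazard group (``median = 0`` is
    disallowed; use ``median = inf``) censors every record.
    """
    rng = np.random.default_rng(seed)
    if np.isinf(params.median):
        times = np.full(params.n, np.inf)
    elif params.distribution == "exponential":
        scale = params.median / np.log(2.0)
        times = rng.exponential(scale, size=params.n)
    else:
        scale = params.median / np.log(2.0) ** (1.0 / params.shape)
        times = scale * rng.weibull(params.shape, size=params.n)
    p = params.inspection_period
    records = []
    for t in times:
        if t > params.study_end:
            records.append(
                IntervalRecord(params.group, float(params.study_end), np.inf)
            )
        else:
            k = int(np.ceil(t / p))
            k = max(k, 1)
            records.append(
                IntervalRecord(params.group, float((k - 1) * p), float(k * p))
            )
    return records


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("fig4d_scaled", "sweep_coarse", "equilibrium_smoke")


def gen_scenario_fixture(name: str) -> ScenarioConfig:
    """Named, fully specified, seeded scenario configurations.

    ``fig4d_scaled``
        Desk-scale suppression comparison: 1,000 adult females, 26 weekly
        releases, 365-day horizon, stochastic, 100 realizations.
    ``sweep_coarse``
        Small population (250 females) pgSIT scenario used for coarse
        competitiveness x lifespan-reduction sweeps.
    ``equilibrium_smoke``
        No releases, 365 days, deterministic stationarity check.
    """
    if name == "fig4d_scaled":
        return ScenarioConfig(
            system="pgsit",
            life_history={"n_female_eq": 1000.0},
            horizon=365,
            mode="stochastic",
            realizations=100,
            n_releases=26,
            seed=1,
        )
    if name == "sweep_coarse":
        return ScenarioConfig(
            system="pgsit",
            life_history={"n_female_eq": 250.0},
            horizon=250,
            mode="stochastic",
            realizations=25,
            n_releases=26,
            seed=1,
        )
    if name == "equilibrium_smoke":
        return ScenarioConfig(
            system="wild",
            horizon=365,
            mode="deterministic",
            realizations=1,
            seed=1,
        )
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
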