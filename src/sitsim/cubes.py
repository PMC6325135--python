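"""Inheritance cubes for genetic-biocontrol release systems.

A cube encodes, for one intervention system, everything the population
model needs to know about genetics and fitness: the offspring
genotype-by-sex distribution of every mother x father cross, the life
stage (if any) at which each genotype-sex class dies, per-genotype male
mating competitiveness, per-genotype adult mortality multipliers, and
the life stage at which the intervention material is released.

Built-in systems
----------------
``wild``
    No intervention; Mendelian wild-type reproduction at a 1:1 sex ratio.
``pgsit``
    Precision-guided SIT. Eggs are released; released females die before
    pupation (larva exit), released males emerge sterile with mating
    competitiveness 0.78 relative to wild males. Matings with sterile
    males yield no viable eggs.
``ridl``
    Release of insects carrying a dominant lethal. Homozygous adult males
    are released with competitiveness 0.05; all their offspring are
    viable as larvae but die at pupal exit.
``fsridl``
    Female-specific RIDL. Homozygous eggs are released; transgene-bearing
    females die at larva exit, carrier males are fertile with Mendelian
    transmission and competitiveness 0.05.
``iit``
    Incompatible insect technique (*Wolbachia*). Adult males are released
    with full competitiveness; cytoplasmic incompatibility makes their
    matings sterile, and irradiation of release batches roughly halves
    their longevity (mortality multiplier 2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: death-stage labels: the point in the life cycle at which a class dies.
DS_NONE = "none"
DS_EGG = "egg"
DS_LARVA_EXIT = "larva_exit"
DS_PUPA_EXIT = "pupa_exit"
DEATH_STAGES = (DS_NONE, DS_EGG, DS_LARVA_EXIT, DS_PUPA_EXIT)

RELEASE_EGG = "egg"
RELEASE_ADULT_MALE = "adult_male"

# genotype labels used by the built-in cubes
WT = "WT"      # wild type
PG = "PG"      # pgSIT released class (trans-heterozygous Cas9/gRNA)
RR = "RR"      # RIDL homozygous released male
RH = "RH"      # RIDL heterozygous offspring (dies at pupal exit)
FF = "FF"      # fsRIDL homozygous released class
FH = "FH"      # fsRIDL heterozygous carrier
II = "II"      # Wolbachia-infected (incompatible) released male

SYSTEMS = ("wild", "pgsit", "ridl", "fsridl", "iit")

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class OffspringDistribution:
    """Offspring classes of one cross and the fraction of eggs that are viable.

    ``entries`` maps (genotype, sex) to a probability. When
    ``viable_egg_fraction`` is 0 the mating is a reproductive dead end and
    ``entries`` is empty: no eggs enter the model at all (eggs that can
    never hatch exert no larval resource pressure, so omitting them is
    equivalent and simpler).
    """

    entries: dict[tuple[str, str], float]
    viable_egg_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.viable_egg_fraction <= 1.0:
            raise ValueError("viable_egg_fraction must be in [0, 1]")


@dataclass(frozen=True)
class InterventionCube:
    """Genetic and fitness rules for one release system.

    ``competitiveness`` (c) scales a male genotype's weight in mate
    choice; ``mortality_multiplier`` (omega) scales the daily adult
    mortality hazard; ``fertile_male`` flags genotypes whose males can
    sire offspring that reach adulthood (this is what 'reproducing
    population' means for elimination).
    """

    name: str
    genotypes: tuple[str, ...]
    cross: dict[tuple[str, str], OffspringDistribution]
    death_stage: dict[tuple[str, str], str]
    competitiveness: dict[str, float]
    mortality_multiplier: dict[str, float]
    fertile_male: dict[str, bool]
    release_stage: str | None = None
    release_genotype: str | None = None

    # -- convenience lookups -------------------------------------------------
    def offspring(self, mother: str, father: str) -> OffspringDistribution:
        return offspring_distribution(self, mother, father)

    def death_stage_of(self, genotype: str, sex: str) -> str:
        return self.death_stage.get((genotype, sex), DS_NONE)

    def c(self, genotype: str) -> float:
        return self.competitiveness.get(genotype, 1.0)

    def omega(self, genotype: str) -> float:
        return self.mortality_multiplier.get(genotype, 1.0)

    def female_reaches_adulthood(self, genotype: str) -> bool:
        return self.death_stage_of(genotype, FEMALE) == DS_NONE

    def male_reaches_adulthood(self, genotype: str) -> bool:
        return self.death_stage_of(genotype, MALE) == DS_NONE

    def reproductive_genotypes(self) -> tuple[str, ...]:
        """Genotypes that can contribute to future reproduction.

        A genotype counts if its females reach adulthood or its males are
        fertile and reach adulthood. The population is considered
        eliminated when all individuals of these genotypes, at any life
        stage, are gone.
        """
        out = []
        for g in self.genotypes:
            if self.female_reaches_adulthood(g):
                out.append(g)
            elif self.fertile_male.get(g, False) and self.male_reaches_adulthood(g):
                out.append(g)
        return tuple(out)

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "genotypes": list(self.genotypes),
            "cross": {
                f"{m}|{f}": {
                    "entries": {f"{g}|{s}": p for (g, s), p in od.entries.items()},
                    "viable_egg_fraction": od.viable_egg_fraction,
                }
                for (m, f), od in self.cross.items()
            },
            "death_stage": {f"{g}|{s}": d for (g, s), d in self.death_stage.items()},
            "competitiveness": dict(self.competitiveness),
            "mortality_multiplier": dict(self.mortality_multiplier),
            "fertile_male": dict(self.fertile_male),
            "release_stage": self.release_stage,
            "release_genotype": self.release_genotype,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "InterventionCube":
        doc = json.loads(text)

        def _split(key: str) -> tuple[str, str]:
            a, b = key.split("|")
            return a, b

        return cls(
            name=doc["name"],
            genotypes=tuple(doc["genotypes"]),
            cross={
                _split(k): OffspringDistribution(
                    entries={_split(ck): p for ck, p in v["entries"].items()},
                    viable_egg_fraction=v["viable_egg_fraction"],
                )
                for k, v in doc["cross"].items()
            },
            death_stage={_split(k): v for k, v in doc["death_stage"].items()},
            competitiveness=doc["competitiveness"],
            mortality_multiplier=doc["mortality_multiplier"],
            fertile_male=doc["fertile_male"],
            release_stage=doc["release_stage"],
            release_genotype=doc["release_genotype"],
        )


def _mendelian(*genotype_probs: tuple[str, float]) -> dict[tuple[str, str], float]:
    """Split genotype probabilities 1:1 into female and male classes."""
    out: dict[tuple[str, str], float] = {}
    for g, p in genotype_probs:
        out[(g, FEMALE)] = 0.5 * p
        out[(g, MALE)] = 0.5 * p
    return out


_STERILE = OffspringDistribution(entries={}, viable_egg_fraction=0.0)


def build_cube(
    system: str,
    c: float | dict[str, float] | None = None,
    omega: float | dict[str, float] | None = None,
    death_stage: dict[tuple[str, str], str] | None = None,
    release_stage: str | None = None,
    released_only_fitness: bool = False,
) -> InterventionCube:
    """Construct a validated cube for one of the built-in systems.

    Parameters
    ----------
    system
        One of ``wild``, ``pgsit``, ``ridl``, ``fsridl``, ``iit``.
    c
        Override of male mating competitiveness. A scalar applies to every
        non-wild genotype; a dict overrides per genotype.
    omega
        Override of the adult mortality-hazard multiplier, same semantics.
    death_stage
        Per (genotype, sex) overrides of the death stage.
    release_stage
        Override of the release stage (``egg`` or ``adult_male``).
    released_only_fitness
        fsRIDL only: if True, the 5% competitiveness is treated as a
        rearing effect of the released stock, so wild-born carrier males
        get c=1 instead of inheriting the genotype-linked value.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")

    wild_cross = OffspringDistribution(entries=_mendelian((WT, 1.0)))

    if system == "wild":
        cube = InterventionCube(
            name="wild",
            genotypes=(WT,),
            cross={(WT, WT): wild_cross},
            death_stage={},
            competitiveness={WT: 1.0},
            mortality_multiplier={WT: 1.0},
            fertile_male={WT: True},
            release_stage=None,
            release_genotype=None,
        )
    elif system == "pgsit":
        cube = InterventionCube(
            name="pgsit",
            genotypes=(WT, PG),
            cross={
                (WT, WT): wild_cross,
                (WT, PG): _STERILE,  # pgSIT males are 100% sterile
            },
            death_stage={(PG, FEMALE): DS_LARVA_EXIT},
            competitiveness={WT: 1.0, PG: 0.78},
            mortality_multiplier={WT: 1.0, PG: 1.0},
            fertile_male={WT: True, PG: False},
            release_stage=RELEASE_EGG,
            release_genotype=PG,
        )
    elif system == "ridl":
        cube = InterventionCube(
            name="ridl",
            genotypes=(WT, RR, RH),
            cross={
                (WT, WT): wild_cross,
                # offspring of released males live as larvae, die at pupal exit
                (WT, RR): OffspringDistribution(entries=_mendelian((RH, 1.0))),
            },
            death_stage={(RH, FEMALE): DS_PUPA_EXIT, (RH, MALE): DS_PUPA_EXIT},
            competitiveness={WT: 1.0, RR: 0.05, RH: 0.05},
            mortality_multiplier={WT: 1.0, RR: 1.0, RH: 1.0},
            # RR males sire eggs, but none of their progeny reach adulthood
            fertile_male={WT: True, RR: False, RH: False},
            release_stage=RELEASE_ADULT_MALE,
            release_genotype=RR,
        )
    elif system == "fsridl":
        carrier_c = 1.0 if released_only_fitness else 0.05
        cube = InterventionCube(
            name="fsridl",
            genotypes=(WT, FF, FH),
            cross={
                (WT, WT): wild_cross,
                (WT, FF): OffspringDistribution(entries=_mendelian((FH, 1.0))),
                (WT, FH): OffspringDistribution(
                    entries=_mendelian((FH, 0.5), (WT, 0.5))
                ),
            },
            death_stage={(FF, FEMALE): DS_LARVA_EXIT, (FH, FEMALE): DS_LARVA_EXIT},
            competitiveness={WT: 1.0, FF: 0.05, FH: carrier_c},
            mortality_multiplier={WT: 1.0, FF: 1.0, FH: 1.0},
            fertile_male={WT: True, FF: True, FH: True},
            release_stage=RELEASE_EGG,
            release_genotype=FF,
        )
    else:  # iit
        cube = InterventionCube(
            name="iit",
            genotypes=(WT, II),
            cross={
                (WT, WT): wild_cross,
                (WT, II): _STERILE,  # cytoplasmic incompatibility
            },
            death_stage={},
            competitiveness={WT: 1.0, II: 1.0},
            mortality_multiplier={WT: 1.0, II: 2.0},
            fertile_male={WT: True, II: False},
            release_stage=RELEASE_ADULT_MALE,
            release_genotype=II,
        )

    cube = _apply_overrides(cube, c, omega, death_stage, release_stage)
    violations = validate_cube(cube)
    if violations:
        raise ValueError("invalid cube after overrides: " + "; ".join(violations))
    return cube


def _apply_overrides(cube, c, omega, death_stage, release_stage):
    comp = dict(cube.competitiveness)
    if c is not None:
        if isinstance(c, dict):
            for g, v in c.items():
                if g not in cube.genotypes:
                    raise ValueError(f"override references undeclared genotype {g!r}")
                comp[g] = float(v)
        else:
            for g in cube.genotypes:
                if g != WT:
                    comp[g] = float(c)
    mort = dict(cube.mortality_multiplier)
    if omega is not None:
        if isinstance(omega, dict):
            for g, v in omega.items():
                if g not in cube.genotypes:
                    raise ValueError(f"override references undeclared genotype {g!r}")
                mort[g] = float(v)
        else:
            for g in cube.genotypes:
                if g != WT:
                    mort[g] = float(omega)
    deaths = dict(cube.death_stage)
    if death_stage is not None:
        for (g, s), d in death_stage.items():
            if g not in cube.genotypes:
                raise ValueError(f"override references undeclared genotype {g!r}")
            if d not in DEATH_STAGES:
                raise ValueError(f"unknown death stage {d!r}")
            deaths[(g, s)] = d
    return replace(
        cube,
        competitiveness=comp,
        mortality_multiplier=mort,
        death_stage=deaths,
        release_stage=release_stage if release_stage is not None else cube.release_stage,
    )


def offspring_distribution(
    cube: InterventionCube, mother: str, father: str
) -> OffspringDistribution:
    """Look up the offspring distribution of a cross, with validation."""
    if mother not in cube.genotypes or father not in cube.genotypes:
        raise KeyError(
            f"unknown genotype pair ({mother!r}, {father!r}) for cube {cube.name!r}"
        )
    try:
        return cube.cross[(mother, father)]
    except KeyError:
        raise KeyError(
            f"cross ({mother!r} x {father!r}) not defined in cube {cube.name!r}"
        ) from None


def validate_cube(cube: InterventionCube) -> list[str]:
    """Check every cube invariant; returns a list of violations (empty = valid)."""
    v: list[str] = []
    gset = set(cube.genotypes)
    for (m, f), od in cube.cross.items():
        label = f"cross ({m} x {f})"
        if m not in gset or f not in gset:
            v.append(f"{label}: parent genotype not declared")
        for (g, s), p in od.entries.items():
            if g not in gset:
                v.append(f"{label}: offspring genotype {g!r} not declared")
            if s not in SEXES:
                v.append(f"{label}: unknown sex {s!r}")
            if p < 0:
                v.append(f"{label}: negative probability for ({g},{s})")
        if od.viable_egg_fraction > 0:
            total = sum(od.entries.values())
            if abs(total - 1.0) > _PROB_TOL:
                v.append(f"{label}: probabilities sum to {total:.6g}, expected 1")
        elif od.entries:
            v.append(f"{label}: viable_egg_fraction=0 but entries non-empty")
    wild = cube.cross.get((WT, WT))
    if wild is None:
        v.append("missing wild x wild cross")
    else:
        expected = _mendelian((WT, 1.0))
        for cls, p in expected.items():
            if abs(wild.entries.get(cls, 0.0) - p) > _PROB_TOL:
                v.append("wild x wild cross is not Mendelian 1:1 wild offspring")
                break
    if abs(cube.competitiveness.get(WT, 1.0) - 1.0) > _PROB_TOL:
        v.append("wild male competitiveness must be 1")
    if abs(cube.mortality_multiplier.get(WT, 1.0) - 1.0) > _PROB_TOL:
        v.append("wild mortality multiplier must be 1")
    for g, cval in cube.competitiveness.items():
        if cval < 0 or not math.isfinite(cval):
            v.append(f"competitiveness of {g} must be finite and >= 0")
    for g, w in cube.mortality_multiplier.items():
        if w < 1.0:
            v.append(f"mortality multiplier of {g} must be >= 1")
    for (g, s), d in cube.death_stage.items():
        if g not in gset:
            v.append(f"death_stage references undeclared genotype {g!r}")
        if d not in DEATH_STAGES:
            v.append(f"unknown death stage {d!r} for ({g},{s})")
    if cube.release_stage not in (None, RELEASE_EGG, RELEASE_ADULT_MALE):
        v.append(f"unknown release stage {cube.release_stage!r}")
    if cube.release_genotype is not None and cube.release_genotype not in gset:
        v.append(f"release genotype {cube.release_genotype!r} not declared")
    return v
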