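"""Daily-time-step agent-based model of a Spotted Wing Drosophila population.

One simulated season runs from early spring to late summer on a daily clock
driven by mean temperature. Individuals progress egg → larva → pupa → adult by
accumulating degree-days above a developmental base; adults mate (females
store sperm from multiple sires with last-male precedence), lay eggs whose
sires are drawn from the sperm store, and die at temperature-dependent rates.
Engineered-genotype viability is enforced at fixed checkpoints:

* EGI-inviable zygotes and RIDL-carrying zygotes (on tetracycline-free field
  food) die at hatch — they are tallied as laid eggs but never enter the
  living population;
* FL-carrying females face the tetracycline dose-response at the larva→pupa
  boundary (field food carries no tetracycline, so only maternally deposited
  exposure can rescue them).

Release strategies cover RIDL, FL, and the three SSIMS rearing regimes
(male-only, single-amplification, double-amplification); the rearing
tetracycline concentration sets the released females' carried exposure and
thereby how many extra field generations the engineered lineage survives.

Internally the population lives in flat numpy arrays for speed; the
:class:`Agent` dataclass is the user-facing record used for cohorts and by
the cage-trial simulator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .environment import TemperatureSeries
from .genetics import (
    Genotype,
    classify,
    cross_distribution,
    fl_female,
    fl_male,
    ridl_female,
    ridl_male,
    ssims_female,
    ssims_male,
    wt_female,
    wt_male,
)
from .tet_dosimetry import TetParams, rearing_steady_state

__all__ = [
    "STAGES",
    "ORIGINS",
    "CLASS_LABELS",
    "Agent",
    "LifecycleParams",
    "MatingParams",
    "ReleaseStrategy",
    "SeasonConfig",
    "SeasonSummary",
    "SimState",
    "released_cohort",
    "update_sperm_store",
    "step_day",
    "run_season",
    "days_to_eradication",
]

STAGES = ("egg", "larva", "pupa", "adult")
ORIGINS = ("wild", "released", "field-born")
CLASS_LABELS = ("WT", "SSIMS", "EGI", "FL", "RIDL", "OTHER")

_EGG, _LARVA, _PUPA, _ADULT = range(4)
_WILD, _RELEASED, _FIELD = range(3)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifecycleParams:
    """Vital rates of the SWD lifecycle.

    Development is degree-day driven above ``dd_base`` with per-stage
    thresholds. Adult daily mortality is a piecewise-linear function of
    temperature: ``mort_opt`` on the benign plateau, rising linearly to
    ``mort_cold`` at and below ``mort_cold_t`` and to ``mort_hot`` at and
    above ``mort_hot_t``; adults also senesce after ``adult_max_days`` days.
    Per-female daily fecundity is a trapezoid in temperature: zero at or
    below ``fec_t0``, rising to ``fec_peak`` at ``fec_t1``, flat to
    ``fec_t2`` and back to zero at ``fec_t3``. Egg survival each day is
    multiplied by ``1 / (1 + L / carrying_capacity)`` where L is the current
    larva count.
    """

    dd_base: float = 7.2
    dd_egg: float = 20.0
    dd_larva: float = 120.0
    dd_pupa: float = 130.0
    juvenile_mortality: float = 0.01
    juvenile_mort_hot: float = 0.25
    juv_hot_lo: float = 23.0
    juv_hot_hi: float = 27.0
    mort_opt: float = 0.03
    mort_opt_lo: float = 10.0
    mort_opt_hi: float = 21.0
    mort_cold: float = 0.03
    mort_cold_t: float = 0.0
    mort_hot: float = 0.40
    mort_hot_t: float = 26.0
    adult_max_days: int = 68
    fec_peak: float = 12.0
    fec_t0: float = 7.2
    fec_t1: float = 12.0
    fec_t2: float = 20.0
    fec_t3: float = 23.0
    carrying_capacity: float = 10000.0

    def __post_init__(self) -> None:
        for name in ("juvenile_mortality", "juvenile_mort_hot", "mort_opt",
                     "mort_cold", "mort_hot"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("dd_egg", "dd_larva", "dd_pupa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")

    def adult_mortality(self, t: float) -> float:
        """Daily adult mortality probability at mean temperature ``t``."""
        if t <= self.mort_cold_t:
            return self.mort_cold
        if t < self.mort_opt_lo:
            w = (t - self.mort_cold_t) / (self.mort_opt_lo - self.mort_cold_t)
            return self.mort_cold + w * (self.mort_opt - self.mort_cold)
        if t <= self.mort_opt_hi:
            return self.mort_opt
        if t < self.mort_hot_t:
            w = (t - self.mort_opt_hi) / (self.mort_hot_t - self.mort_opt_hi)
            return self.mort_opt + w * (self.mort_hot - self.mort_opt)
        return self.mort_hot

    def juvenile_mortality_at(self, t: float) -> float:
        """Daily juvenile mortality: a flat background plus a heat ramp
        between ``juv_hot_lo`` and ``juv_hot_hi``."""
        base = self.juvenile_mortality
        if t <= self.juv_hot_lo:
            return base
        if t >= self.juv_hot_hi:
            return base + self.juvenile_mort_hot
        w = (t - self.juv_hot_lo) / (self.juv_hot_hi - self.juv_hot_lo)
        return base + w * self.juvenile_mort_hot

    def fecundity(self, t: float) -> float:
        """Expected eggs laid per mated female per day at temperature ``t``."""
        if t <= self.fec_t0 or t >= self.fec_t3:
            return 0.0
        if t < self.fec_t1:
            return self.fec_peak * (t - self.fec_t0) / (self.fec_t1 - self.fec_t0)
        if t <= self.fec_t2:
            return self.fec_peak
        return self.fec_peak * (self.fec_t3 - t) / (self.fec_t3 - self.fec_t2)


@dataclass(frozen=True)
class MatingParams:
    """Daily mating behavior: virgin mating and remating probabilities and
    last-male sperm precedence P2."""

    p_mate: float = 0.8
    p_remate: float = 0.03
    p2: float = 0.8

    def __post_init__(self) -> None:
        for name in ("p_mate", "p_remate", "p2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: kind -> (female template, male template, female fraction,
#:          rearing tet μg/ml, hatching tet μg/ml)
_STRATEGY_KINDS: dict[str, tuple] = {
    "RIDL": (ridl_female, ridl_male, 0.5, 100.0, 100.0),
    "FL": (fl_female, fl_male, 0.5, 100.0, 100.0),
    "SSIMS_male_only": (ssims_female, ssims_male, 0.0, 10.0, 0.0),
    "SSIMS_single_amp": (ssims_female, ssims_male, 0.5, 10.0, 10.0),
    "SSIMS_double_amp": (ssims_female, ssims_male, 0.5, 100.0, 100.0),
}


@dataclass(frozen=True)
class ReleaseStrategy:
    """A release programme: which strain, how many, how often, over what window.

    ``rearing_tet`` / ``hatching_tet`` / ``female_fraction`` default per kind
    (male-only SSIMS hatches on tet-free food so only males survive to be
    released; bi-sex releases use an exact ⌊n·f⌋ female split).
    """

    kind: str = "none"
    size: int = 0
    interval: int = 7
    rearing_tet: Optional[float] = None
    hatching_tet: Optional[float] = None
    female_fraction: Optional[float] = None
    window_start: Optional[dt.date] = None
    window_end: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.kind != "none" and self.kind not in _STRATEGY_KINDS:
            raise ValueError(
                f"unknown release kind {self.kind!r}; "
                f"expected one of {'none', *_STRATEGY_KINDS}"
            )
        if self.size < 0:
            raise ValueError("release size must be >= 0")
        if self.interval < 1:
            raise ValueError("release interval must be >= 1 day")

    def resolved(self) -> "ReleaseStrategy":
        """Fill kind-dependent defaults."""
        if self.kind == "none":
            return self
        _, _, ff, rear, hatch = _STRATEGY_KINDS[self.kind]
        return replace(
            self,
            female_fraction=ff if self.female_fraction is None else self.female_fraction,
            rearing_tet=rear if self.rearing_tet is None else self.rearing_tet,
            hatching_tet=hatch if self.hatching_tet is None else self.hatching_tet,
        )


@dataclass(frozen=True)
class SeasonConfig:
    """Configuration of one simulated season."""

    lifecycle: LifecycleParams = field(default_factory=LifecycleParams)
    mating: MatingParams = field(default_factory=MatingParams)
    tet: TetParams = field(default_factory=TetParams)
    strategy: ReleaseStrategy = field(default_factory=ReleaseStrategy)
    initial_adults: int = 100
    start: Optional[dt.date] = None
    end: Optional[dt.date] = None


# ---------------------------------------------------------------------------
# Public agent record
# ---------------------------------------------------------------------------

@dataclass
class Agent:
    """One fly, as a user-facing record.

    ``sperm_store`` is a sequence of ``(sire genotype, weight)`` pairs with
    weights summing to 1 for mated females and empty otherwise.
    """

    genotype: Genotype
    stage: str = "adult"
    degree_days: float = 0.0
    tet_exposure: float = 0.0
    sperm_store: tuple[tuple[Genotype, float], ...] = ()
    days_adult: int = 0
    origin: str = "wild"
    generation: int = 0
    alive: bool = True

    @property
    def sex(self) -> str:
        return "female" if self.genotype.is_female else "male"


def update_sperm_store(
    store: Sequence[tuple[Genotype, float]], new_sire: Genotype, p2: float
) -> tuple[tuple[Genotype, float], ...]:
    """Last-male sperm precedence: the new sire takes weight ``p2`` and all
    prior weights are scaled by ``1 - p2``; a first mating takes weight 1."""
    if not (0.0 <= p2 <= 1.0):
        raise ValueError(f"p2 must be in [0, 1], got {p2}")
    if not store:
        return ((new_sire, 1.0),)
    out = [(g, w * (1.0 - p2)) for g, w in store]
    out.append((new_sire, p2))
    return tuple(out)


def released_cohort(
    strategy: ReleaseStrategy,
    n: int,
    rng: np.random.Generator,
    tet: TetParams | None = None,
) -> list[Agent]:
    """Build a release cohort of ``n`` adults for the strategy.

    Released individuals carry the tetracycline exposure of a stock
    maintained at the strategy's rearing concentration. The female count is
    the exact floor split for reproducibility; ``rng`` is accepted for
    interface symmetry with the stochastic operations.
    """
    del rng  # exact split: no randomness needed
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    if strategy.kind == "none" or n == 0:
        return []
    strategy = strategy.resolved()
    f_tpl, m_tpl, _, _, _ = _STRATEGY_KINDS[strategy.kind]
    tet = tet or TetParams()
    e = rearing_steady_state(float(strategy.rearing_tet), tet)
    n_f = int(np.floor(n * float(strategy.female_fraction)))
    agents = [
        Agent(genotype=f_tpl(), tet_exposure=e, origin="released")
        for _ in range(n_f)
    ]
    agents += [
        Agent(genotype=m_tpl(), tet_exposure=e, origin="released")
        for _ in range(n - n_f)
    ]
    return agents


# ---------------------------------------------------------------------------
# Internal genotype registry and vectorized state
# ---------------------------------------------------------------------------

class _GenotypeTable:
    """Interns genotypes to integer codes with cached per-code attributes."""

    def __init__(self) -> None:
        self._codes: dict[Genotype, int] = {}
        self.genotypes: list[Genotype] = []
        self._female: list[bool] = []
        self._has_fl: list[bool] = []
        self._has_ridl: list[bool] = []
        self._engineered: list[bool] = []
        self._class_idx: list[int] = []
        self._arrays: dict[str, np.ndarray] | None = None
        self._cross: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.genotypes)

    def code(self, g: Genotype) -> int:
        c = self._codes.get(g)
        if c is None:
            c = len(self.genotypes)
            self._codes[g] = c
            self.genotypes.append(g)
            self._female.append(g.is_female)
            self._has_fl.append(g.has_fl)
            self._has_ridl.append(g.has_ridl)
            self._engineered.append(g.is_engineered)
            self._class_idx.append(CLASS_LABELS.index(classify(g)))
            self._arrays = None
        return c

    def arrays(self) -> dict[str, np.ndarray]:
        if self._arrays is None:
            self._arrays = {
                "female": np.array(self._female, dtype=bool),
                "has_fl": np.array(self._has_fl, dtype=bool),
                "has_ridl": np.array(self._has_ridl, dtype=bool),
                "engineered": np.array(self._engineered, dtype=bool),
                "class_idx": np.array(self._class_idx, dtype=np.int8),
            }
        return self._arrays

    def cross(self, mom: int, dad: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(offspring codes, probabilities, egi-viability) for a parental pair."""
        key = (mom, dad)
        hit = self._cross.get(key)
        if hit is None:
            dist = cross_distribution(self.genotypes[mom], self.genotypes[dad])
            codes = np.array([self.code(g) for g, _, _ in dist], dtype=np.int64)
            probs = np.array([p for _, p, _ in dist], dtype=float)
            viab = np.array([v for _, _, v in dist], dtype=bool)
            hit = (codes, probs, viab)
            self._cross[key] = hit
        return hit


class SimState:
    """Mutable population state: flat arrays plus running season counters."""

    def __init__(
        self,
        lifecycle: LifecycleParams | None = None,
        mating: MatingParams | None = None,
        tet: TetParams | None = None,
    ) -> None:
        self.lifecycle = lifecycle or LifecycleParams()
        self.mating = mating or MatingParams()
        self.tet = tet or TetParams()
        self.table = _GenotypeTable()
        self.code = np.zeros(0, dtype=np.int64)
        self.stage = np.zeros(0, dtype=np.int8)
        self.dd = np.zeros(0, dtype=float)
        self.exposure = np.zeros(0, dtype=float)
        self.adult_age = np.zeros(0, dtype=np.int32)
        self.origin = np.zeros(0, dtype=np.int8)
        self.generation = np.zeros(0, dtype=np.int32)
        self.alive = np.zeros(0, dtype=bool)
        self.sperm = np.zeros((0, 0), dtype=float)
        # season counters
        self.cumulative_wt_hatched = 0
        self.fieldborn_gm_created = 0
        self.gm_female_pupae_by_gen: dict[int, int] = {}
        self.day_eggs_laid = 0
        self.day_eggs_inviable = 0

    # -- bookkeeping ------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.alive.sum())

    def _ensure_sperm_width(self) -> None:
        width = len(self.table)
        if self.sperm.shape[1] < width:
            pad = np.zeros((self.sperm.shape[0], width - self.sperm.shape[1]))
            self.sperm = np.hstack([self.sperm, pad])

    def _append_raw(
        self,
        codes: np.ndarray,
        stage: int,
        exposure: np.ndarray,
        origin: int,
        generation: np.ndarray,
        sperm_rows: np.ndarray | None = None,
    ) -> None:
        k = codes.size
        if k == 0:
            return
        self._ensure_sperm_width()
        width = self.sperm.shape[1]
        self.code = np.concatenate([self.code, codes.astype(np.int64)])
        self.stage = np.concatenate([self.stage, np.full(k, stage, dtype=np.int8)])
        self.dd = np.concatenate([self.dd, np.zeros(k)])
        self.exposure = np.concatenate([self.exposure, np.asarray(exposure, dtype=float)])
        self.adult_age = np.concatenate([self.adult_age, np.zeros(k, dtype=np.int32)])
        self.origin = np.concatenate([self.origin, np.full(k, origin, dtype=np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.asarray(generation, dtype=np.int32)]
        )
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        if sperm_rows is None:
            sperm_rows = np.zeros((k, width))
        self.sperm = np.vstack([self.sperm, sperm_rows])

    def add_agents(self, agents: Sequence[Agent]) -> None:
        """Insert user-level agents (used for seeding and releases)."""
        if not agents:
            return
        codes = np.array([self.table.code(a.genotype) for a in agents], dtype=np.int64)
        for a in agents:  # register sire genotypes before sizing the matrix
            for sire, _ in a.sperm_store:
                self.table.code(sire)
        self._ensure_sperm_width()
        width = max(self.sperm.shape[1], len(self.table))
        rows = np.zeros((len(agents), width))
        for i, a in enumerate(agents):
            for sire, w in a.sperm_store:
                rows[i, self.table.code(sire)] += w
        self._append_raw(
            codes,
            stage=STAGES.index(agents[0].stage),
            exposure=np.array([a.tet_exposure for a in agents]),
            origin=ORIGINS.index(agents[0].origin),
            generation=np.array([a.generation for a in agents]),
            sperm_rows=rows,
        )

    def compact(self) -> None:
        keep = self.alive
        if keep.all():
            return
        self.code = self.code[keep]
        self.stage = self.stage[keep]
        self.dd = self.dd[keep]
        self.exposure = self.exposure[keep]
        self.adult_age = self.adult_age[keep]
        self.origin = self.origin[keep]
        self.generation = self.generation[keep]
        self.sperm = self.sperm[keep]
        self.alive = self.alive[keep]

    def census(self) -> np.ndarray:
        """Living counts indexed (class, sex, stage, origin); sex 0=female."""
        out = np.zeros((len(CLASS_LABELS), 2, len(STAGES), len(ORIGINS)), dtype=np.int64)
        if self.code.size == 0:
            return out
        tab = self.table.arrays()
        rows = np.where(self.alive)[0]
        cls = tab["class_idx"][self.code[rows]].astype(np.int64)
        sex = (~tab["female"][self.code[rows]]).astype(np.int64)
        key = ((cls * 2 + sex) * len(STAGES) + self.stage[rows]) * len(ORIGINS) + self.origin[
            rows
        ]
        flat = np.bincount(key, minlength=out.size)
        return flat.reshape(out.shape)

    def agents(self) -> list[Agent]:
        """Materialise the living population as user-level records."""
        out: list[Agent] = []
        tab = self.table
        for i in np.where(self.alive)[0]:
            store = tuple(
                (tab.genotypes[j], float(w))
                for j, w in enumerate(self.sperm[i])
                if w > 0
            )
            out.append(
                Agent(
                    genotype=tab.genotypes[int(self.code[i])],
                    stage=STAGES[int(self.stage[i])],
                    degree_days=float(self.dd[i]),
                    tet_exposure=float(self.exposure[i]),
                    sperm_store=store,
                    days_adult=int(self.adult_age[i]),
                    origin=ORIGINS[int(self.origin[i])],
                    generation=int(self.generation[i]),
                )
            )
        return out


def _female_survival_vec(e: np.ndarray, p: TetParams) -> np.ndarray:
    s = np.zeros_like(e)
    hot = e >= p.e_floor
    eh = e[hot] ** p.hill_h
    s[hot] = p.s_max * eh / (p.ec50**p.hill_h + eh)
    return s


def step_day(state: SimState, temperature: float, rng: np.random.Generator) -> SimState:
    """Advance the population by one day at the given mean temperature.

    Sub-steps in order: degree-day accrual and stage promotion (with FL/RIDL
    viability enforced at the larva→pupa boundary), background and
    temperature-dependent mortality, mating and sperm-store updates,
    oviposition (EGI-inviable zygotes tallied but not instantiated), and
    density-dependent egg survival.
    """
    lc, mp, tp = state.lifecycle, state.mating, state.tet
    state.day_eggs_laid = 0
    state.day_eggs_inviable = 0
    if state.code.size == 0:
        return state
    tab = state.table.arrays()
    alive = state.alive
    is_f = tab["female"][state.code]
    has_fl = tab["has_fl"][state.code]
    has_ridl = tab["has_ridl"][state.code]
    engineered = tab["engineered"][state.code]
    is_wt = ~engineered

    # (1) degree-day accrual and promotion, oldest stage first so nobody
    # advances twice in one day
    gain = max(0.0, temperature - lc.dd_base)
    juv = alive & (state.stage < _ADULT)
    state.dd[juv] += gain

    rows = np.where(alive & (state.stage == _PUPA) & (state.dd >= lc.dd_pupa))[0]
    if rows.size:
        state.stage[rows] = _ADULT
        state.dd[rows] = 0.0
        state.adult_age[rows] = 0
        state.cumulative_wt_hatched += int(np.count_nonzero(is_wt[rows]))

    # (2) larva→pupa boundary: FL dose-response for females, RIDL lethality
    rows = np.where(alive & (state.stage == _LARVA) & (state.dd >= lc.dd_larva))[0]
    if rows.size:
        die = np.zeros(rows.size, dtype=bool)
        flf = is_f[rows] & has_fl[rows]
        if flf.any():
            p_surv = _female_survival_vec(state.exposure[rows[flf]], tp)
            die[flf] |= rng.random(int(flf.sum())) >= p_surv
        alive[rows[die]] = False
        live = rows[~die]
        state.stage[live] = _PUPA
        state.dd[live] -= lc.dd_larva
        gmf = live[is_f[live] & engineered[live] & (state.origin[live] == _FIELD)]
        if gmf.size:
            gens, cnts = np.unique(state.generation[gmf], return_counts=True)
            for g, c in zip(gens, cnts):
                state.gm_female_pupae_by_gen[int(g)] = (
                    state.gm_female_pupae_by_gen.get(int(g), 0) + int(c)
                )

    rows = np.where(alive & (state.stage == _EGG) & (state.dd >= lc.dd_egg))[0]
    if rows.size:
        state.stage[rows] = _LARVA
        state.dd[rows] -= lc.dd_egg

    # (3) mortality
    juv = np.where(alive & (state.stage < _ADULT))[0]
    if juv.size:
        alive[juv[rng.random(juv.size) < lc.juvenile_mortality_at(temperature)]] = False
    ad = np.where(alive & (state.stage == _ADULT))[0]
    if ad.size:
        state.adult_age[ad] += 1
        m = lc.adult_mortality(temperature)
        dead = rng.random(ad.size) < m
        dead |= state.adult_age[ad] > lc.adult_max_days
        alive[ad[dead]] = False

    # (4) mating: sire drawn uniformly over living adult males
    state._ensure_sperm_width()
    ad_mask = alive & (state.stage == _ADULT)
    males = np.where(ad_mask & ~is_f)[0]
    females = np.where(ad_mask & is_f)[0]
    if males.size and females.size:
        m_codes, m_counts = np.unique(state.code[males], return_counts=True)
        m_probs = m_counts / m_counts.sum()
        mated = state.sperm[females].sum(axis=1) > 0
        p = np.where(mated, mp.p_remate, mp.p_mate)
        does = rng.random(females.size) < p
        maters = females[does]
        if maters.size:
            sires = rng.choice(m_codes, size=maters.size, p=m_probs)
            first = ~mated[does]
            v_rows, v_sires = maters[first], sires[first]
            state.sperm[v_rows, v_sires] = 1.0
            r_rows, r_sires = maters[~first], sires[~first]
            if r_rows.size:
                state.sperm[r_rows] = state.sperm[r_rows] * (1.0 - mp.p2)
                state.sperm[r_rows, r_sires] += mp.p2

    # (5) oviposition
    fec = lc.fecundity(temperature)
    if fec > 0 and females.size:
        sums = state.sperm[females].sum(axis=1)
        moms = females[sums > 0]
        if moms.size:
            n_eggs = rng.poisson(fec, moms.size)
            total = int(n_eggs.sum())
            if total:
                mom_rows = np.repeat(moms, n_eggs)
                w = state.sperm[mom_rows]
                c = np.cumsum(w, axis=1)
                u = rng.random(total) * c[:, -1]
                dad_codes = (c < u[:, None]).sum(axis=1).astype(np.int64)
                mom_codes = state.code[mom_rows]
                width = np.int64(len(state.table))
                pair_key = mom_codes * width + dad_codes
                child = np.empty(total, dtype=np.int64)
                viable = np.empty(total, dtype=bool)
                for k in np.unique(pair_key):
                    sel = pair_key == k
                    mc, dc = divmod(int(k), int(width))
                    codes, probs, viab = state.table.cross(mc, dc)
                    pick = rng.choice(codes.size, size=int(sel.sum()), p=probs)
                    child[sel] = codes[pick]
                    viable[sel] = viab[pick]
                # RIDL zygotes on tet-free field food die at hatch, like
                # EGI-inviable hybrids
                viable &= ~state.table.arrays()["has_ridl"][child]
                state.day_eggs_laid = total
                state.day_eggs_inviable = int((~viable).sum())
                keep = viable
                new_codes = child[keep]
                new_e = tp.kappa * state.exposure[mom_rows][keep]
                new_gen = state.generation[mom_rows][keep] + 1
                state._append_raw(
                    new_codes, stage=_EGG, exposure=new_e, origin=_FIELD, generation=new_gen
                )
                alive = state.alive  # arrays grew: rebind the local view
                gm_new = state.table.arrays()["engineered"][new_codes]
                state.fieldborn_gm_created += int(gm_new.sum())

    # (6) density-dependent egg survival
    larvae = int(np.count_nonzero(alive & (state.stage == _LARVA)))
    eggs = np.where(alive & (state.stage == _EGG))[0]
    if eggs.size:
        p_surv = 1.0 / (1.0 + larvae / lc.carrying_capacity)
        alive[eggs[rng.random(eggs.size) >= p_surv]] = False

    state.alive = alive
    state.compact()
    return state


# ---------------------------------------------------------------------------
# Season driver
# ---------------------------------------------------------------------------

@dataclass
class SeasonSummary:
    """Daily censuses and season-level counters from one run."""

    start: dt.date
    counts: np.ndarray  # (day, class, sex, stage, origin)
    eggs_laid: np.ndarray
    eggs_inviable: np.ndarray
    cumulative_wt_hatched: int
    fieldborn_gm_created: int
    gm_female_pupae_by_gen: dict[int, int]
    seed: int

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    @property
    def wt_alive(self) -> np.ndarray:
        """Wild-type individuals of any stage, per day."""
        return self.counts[:, CLASS_LABELS.index("WT")].sum(axis=(1, 2, 3))

    @property
    def gm_alive(self) -> np.ndarray:
        """Engineered individuals (all non-WT classes), per day."""
        wt = CLASS_LABELS.index("WT")
        sel = [i for i in range(len(CLASS_LABELS)) if i != wt]
        return self.counts[:, sel].sum(axis=(1, 2, 3, 4))

    @property
    def total_alive(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2, 3, 4))

    def to_tidy(self) -> pd.DataFrame:
        """Long-format daily census: day (1-based), date, class, sex, stage,
        origin, count — zero rows omitted."""
        d, c, s, st, o = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "day": d + 1,
                "date": [self.start + dt.timedelta(days=int(i)) for i in d],
                "class": [CLASS_LABELS[i] for i in c],
                "sex": ["female" if i == 0 else "male" for i in s],
                "stage": [STAGES[i] for i in st],
                "origin": [ORIGINS[i] for i in o],
                "count": self.counts[d, c, s, st, o],
            }
        )

    def summary_row(self) -> pd.DataFrame:
        day = days_to_eradication(self)
        return pd.DataFrame(
            [
                {
                    "cumulative_wt_hatched": self.cumulative_wt_hatched,
                    "days_to_eradication": np.nan if day is None else day,
                    "seed": self.seed,
                }
            ]
        )


def _release_days(strategy: ReleaseStrategy, start: dt.date, end: dt.date) -> set[int]:
    if strategy.kind == "none" or strategy.size == 0:
        return set()
    w0 = strategy.window_start or start
    w1 = strategy.window_end or end
    d0 = max((w0 - start).days, 0)
    d1 = min((w1 - start).days, (end - start).days)
    return set(range(d0, d1 + 1, strategy.interval))


def run_season(
    config: SeasonConfig, temperature: TemperatureSeries, seed: int
) -> SeasonSummary:
    """Simulate one season and return its summary.

    Day 1 seeds the initial wild adults (even female:male split, females
    pre-mated to wild males); releases occur per the strategy schedule at the
    start of the scheduled day; identical seed and configuration give
    bit-identical summaries.
    """
    rng = np.random.default_rng(seed)
    start = config.start or temperature.start
    end = config.end or temperature.end
    temps = temperature.slice(start, end)
    n_days = len(temps)
    strategy = config.strategy.resolved() if config.strategy.kind != "none" else config.strategy
    state = SimState(config.lifecycle, config.mating, config.tet)

    n0 = config.initial_adults
    n_f = n0 // 2
    wm, wf = wt_male(), wt_female()
    seeds = [
        Agent(genotype=wf, origin="wild", sperm_store=((wm, 1.0),)) for _ in range(n_f)
    ]
    seeds += [Agent(genotype=wm, origin="wild") for _ in range(n0 - n_f)]
    state.add_agents(seeds)

    rel_days = _release_days(strategy, start, end)
    counts = np.zeros(
        (n_days, len(CLASS_LABELS), 2, len(STAGES), len(ORIGINS)), dtype=np.int64
    )
    eggs_laid = np.zeros(n_days, dtype=np.int64)
    eggs_inviable = np.zeros(n_days, dtype=np.int64)
    for d in range(n_days):
        if d in rel_days:
            state.add_agents(released_cohort(strategy, strategy.size, rng, config.tet))
        step_day(state, float(temps.tmean[d]), rng)
        counts[d] = state.census()
        eggs_laid[d] = state.day_eggs_laid
        eggs_inviable[d] = state.day_eggs_inviable
    return SeasonSummary(
        start=start,
        counts=counts,
        eggs_laid=eggs_laid,
        eggs_inviable=eggs_inviable,
        cumulative_wt_hatched=state.cumulative_wt_hatched,
        fieldborn_gm_created=state.fieldborn_gm_created,
        gm_female_pupae_by_gen=dict(state.gm_female_pupae_by_gen),
        seed=seed,
    )


def days_to_eradication(summary: SeasonSummary | np.ndarray) -> Optional[int]:
    """First day (1-based) from which the wild-type count stays at zero.

    Returns ``None`` when wild-type individuals remain on the final day
    ("not reached").
    """
    wt = summary.wt_alive if isinstance(summary, SeasonSummary) else np.asarray(summary)
    nz = np.nonzero(wt)[0]
    if nz.size == 0:
        return 1
    last = int(nz[-1])
    if last == len(wt) - 1:
        return None
    return last + 2
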