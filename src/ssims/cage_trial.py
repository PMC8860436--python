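"""Discrete-event simulator of the laboratory cage-suppression protocol.

The protocol: cages seeded with virgin wild-type adults, weekly additions of
tetracycline-reared SSIMS adults for the first eight weeks, a 24-hour
reproduction bottle each week whose brood ecloses into the cage 10–13 days
later, a weekly yeast/sugar trap that removes a fixed fraction of adults, and
a weekly fecundity assay on up to ten trapped wild-type females (assayed in
individual vials for three days, then returned to the cage). The cage sits at
a constant rearing temperature, so only adult dynamics and bottle broods need
simulating — juveniles develop inside scheduled bottle cohorts.

Suppression emerges from the genetics: wild-type females inseminated by SSIMS
males produce only EGI-inviable zygotes, SSIMS×SSIMS daughters inherit a
decaying share of maternal tetracycline, and sperm displacement lets late
SSIMS matings overwrite earlier wild-type inseminations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import Genotype, ridl_viable, ssims_female, ssims_male, wt_female, wt_male
from .swd_abm import Agent, MatingParams, _GenotypeTable, CLASS_LABELS
from .tet_dosimetry import TetParams, female_survival, rearing_steady_state

__all__ = ["CageConfig", "WeeklyRecord", "run_cage", "fecundity_assay"]


@dataclass(frozen=True)
class CageConfig:
    """Cage-trial protocol parameters (counts, schedules, and rates)."""

    initial_wild: int = 600                 # 50:50 virgin females:males
    weekly_addition: int = 600              # SSIMS adults per release week
    addition_female_fraction: float = 0.45
    release_weeks: tuple[int, ...] = tuple(range(1, 9))  # 1-based weeks
    rearing_tet: float = 100.0              # μg/ml for the released stock
    trap_probability: float = 0.25
    eclosion_lag_days: int = 10
    emergence_window_days: int = 3
    assay_females: int = 10
    assay_absence_days: int = 3
    weeks: int = 16
    adult_mortality: float = 0.05           # daily, at constant 25 °C (crowded cage)
    adult_max_days: int = 60
    bottle_fecundity: float = 25.0          # eggs per mated female in the 24 h lay
    bottle_cap: int = 800                   # max emergers per bottle
    juvenile_survival: float = 0.90         # egg-to-eclosion background survival
    assay_fecundity_mean: float = 75.0      # expected eggs over the 3-day vial lay
    # Remating and displacement are stronger in the confined cage, where
    # males are always abundant, than the field defaults: full sperm
    # displacement builds up over a few days of cohabitation.
    mating: MatingParams = field(
        default_factory=lambda: MatingParams(p_remate=0.25, p2=0.9)
    )
    tet: TetParams = field(default_factory=TetParams)

    def __post_init__(self) -> None:
        for name in ("trap_probability", "adult_mortality", "juvenile_survival",
                     "addition_female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")


@dataclass
class WeeklyRecord:
    """One week of observations: trap counts, assay results, and the census."""

    week: int
    trap_counts: dict[tuple[str, str], int]
    fecundity_counts: list[int]
    census: dict[tuple[str, str], int]

    def trap(self, label: str, sex: str) -> int:
        return self.trap_counts.get((label, sex), 0)

    def in_census(self, label: str, sex: str) -> int:
        return self.census.get((label, sex), 0)


def fecundity_assay(
    female: Agent,
    rng: np.random.Generator,
    mean_eggs: float = 75.0,
    tet: TetParams | None = None,
) -> int:
    """Offspring surviving to adulthood from one assayed female.

    Eggs over the vial lay are Poisson with the calibrated mean; each egg's
    sire is drawn from the female's sperm-store weights and the offspring is
    kept only if it passes EGI, RIDL (tet-free vial food) and, for
    FL-carrying daughters, the maternal-carryover dose-response. An unmated
    female yields zero (her eggs are unfertilized).
    """
    if not female.genotype.is_female:
        raise ValueError("fecundity assay requires a female")
    tet = tet or TetParams()
    store = female.sperm_store
    if not store:
        return 0
    n_eggs = int(rng.poisson(mean_eggs))
    if n_eggs == 0:
        return 0
    sires = [g for g, _ in store]
    weights = np.array([w for _, w in store], dtype=float)
    weights = weights / weights.sum()
    table = _GenotypeTable()
    mom_code = table.code(female.genotype)
    child_e = tet.kappa * female.tet_exposure
    survivors = 0
    sire_draws = rng.choice(len(sires), size=n_eggs, p=weights)
    for si in sire_draws:
        codes, probs, viable = table.cross(mom_code, table.code(sires[si]))
        k = int(rng.choice(codes.size, p=probs))
        if not viable[k]:
            continue
        g = table.genotypes[int(codes[k])]
        if not ridl_viable(g, 0.0):
            continue
        if g.is_female and g.has_fl:
            if rng.random() >= female_survival(child_e, tet):
                continue
        survivors += 1
    return survivors


class _CageState:
    """Adults-only struct-of-arrays population for the cage."""

    def __init__(self, tet: TetParams) -> None:
        self.table = _GenotypeTable()
        self.tet = tet
        self.code = np.zeros(0, dtype=np.int64)
        self.exposure = np.zeros(0, dtype=float)
        self.age = np.zeros(0, dtype=np.int32)
        self.generation = np.zeros(0, dtype=np.int32)
        self.alive = np.zeros(0, dtype=bool)
        self.sperm = np.zeros((0, 0), dtype=float)

    def _ensure_width(self) -> None:
        width = len(self.table)
        if self.sperm.shape[1] < width:
            pad = np.zeros((self.sperm.shape[0], width - self.sperm.shape[1]))
            self.sperm = np.hstack([self.sperm, pad])

    def append(
        self,
        codes: np.ndarray,
        exposure: np.ndarray,
        generation: np.ndarray,
        age: np.ndarray | None = None,
        sperm_rows: np.ndarray | None = None,
    ) -> None:
        k = codes.size
        if k == 0:
            return
        self._ensure_width()
        width = self.sperm.shape[1]
        self.code = np.concatenate([self.code, codes.astype(np.int64)])
        self.exposure = np.concatenate([self.exposure, np.asarray(exposure, float)])
        self.age = np.concatenate(
            [self.age, np.zeros(k, np.int32) if age is None else np.asarray(age, np.int32)]
        )
        self.generation = np.concatenate(
            [self.generation, np.asarray(generation, np.int32)]
        )
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        if sperm_rows is None:
            sperm_rows = np.zeros((k, width))
        elif sperm_rows.shape[1] < width:
            sperm_rows = np.hstack(
                [sperm_rows, np.zeros((sperm_rows.shape[0], width - sperm_rows.shape[1]))]
            )
        self.sperm = np.vstack([self.sperm, sperm_rows])

    def compact(self) -> None:
        keep = self.alive
        if keep.all():
            return
        self.code = self.code[keep]
        self.exposure = self.exposure[keep]
        self.age = self.age[keep]
        self.generation = self.generation[keep]
        self.sperm = self.sperm[keep]
        self.alive = self.alive[keep]

    def counts_by_class_sex(self, rows: np.ndarray) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        tab = self.table.arrays()
        for r in rows:
            label = CLASS_LABELS[int(tab["class_idx"][self.code[r]])]
            sex = "female" if tab["female"][self.code[r]] else "male"
            out[(label, sex)] = out.get((label, sex), 0) + 1
        return out


def _daily_adults(state: _CageState, cfg: CageConfig, rng: np.random.Generator) -> None:
    """One cage day: mortality, senescence, then mating."""
    rows = np.where(state.alive)[0]
    if rows.size == 0:
        return
    state.age[rows] += 1
    dead = rng.random(rows.size) < cfg.adult_mortality
    dead |= state.age[rows] > cfg.adult_max_days
    state.alive[rows[dead]] = False
    state.compact()
    state._ensure_width()
    tab = state.table.arrays()
    is_f = tab["female"][state.code]
    males = np.where(state.alive & ~is_f)[0]
    females = np.where(state.alive & is_f)[0]
    if males.size == 0 or females.size == 0:
        return
    mp = cfg.mating
    m_codes, m_counts = np.unique(state.code[males], return_counts=True)
    m_probs = m_counts / m_counts.sum()
    mated = state.sperm[females].sum(axis=1) > 0
    p = np.where(mated, mp.p_remate, mp.p_mate)
    does = rng.random(females.size) < p
    maters = females[does]
    if maters.size == 0:
        return
    sires = rng.choice(m_codes, size=maters.size, p=m_probs)
    first = ~mated[does]
    state.sperm[maters[first], sires[first]] = 1.0
    r_rows, r_sires = maters[~first], sires[~first]
    if r_rows.size:
        state.sperm[r_rows] = state.sperm[r_rows] * (1.0 - mp.p2)
        state.sperm[r_rows, r_sires] += mp.p2


def _bottle_brood(
    state: _CageState, cfg: CageConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offspring that will eclose from this week's reproduction bottle.

    Returns (codes, exposures, generations) of the survivors after EGI, RIDL,
    FL, background juvenile mortality and the bottle density cap.
    """
    tab = state.table.arrays()
    is_f = tab["female"][state.code]
    females = np.where(state.alive & is_f)[0]
    empty = (np.zeros(0, np.int64), np.zeros(0), np.zeros(0, np.int32))
    if females.size == 0:
        return empty
    sums = state.sperm[females].sum(axis=1)
    moms = females[sums > 0]
    if moms.size == 0:
        return empty
    n_eggs = rng.poisson(cfg.bottle_fecundity, moms.size)
    total = int(n_eggs.sum())
    if total == 0:
        return empty
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
    child_e = cfg.tet.kappa * state.exposure[mom_rows]
    child_gen = state.generation[mom_rows] + 1
    # EGI at hatch
    keep = viable.copy()
    tab = state.table.arrays()  # may have grown via cross()
    # RIDL on tet-free bottle food, both sexes
    keep &= ~tab["has_ridl"][child]
    # FL daughters face the dose-response on maternal carryover alone
    flf = keep & tab["female"][child] & tab["has_fl"][child]
    if flf.any():
        e = child_e[flf]
        p_surv = np.where(
            e < cfg.tet.e_floor,
            0.0,
            cfg.tet.s_max * e**cfg.tet.hill_h / (cfg.tet.ec50**cfg.tet.hill_h + e**cfg.tet.hill_h),
        )
        keep[np.where(flf)[0][rng.random(int(flf.sum())) >= p_surv]] = False
    # background egg-to-adult survival in the bottle
    idx = np.where(keep)[0]
    idx = idx[rng.random(idx.size) < cfg.juvenile_survival]
    # density cap: the bottle supports only so many emergers
    if idx.size > cfg.bottle_cap:
        idx = rng.choice(idx, size=cfg.bottle_cap, replace=False)
        idx.sort()
    return child[idx], child_e[idx], child_gen[idx]


def run_cage(config: CageConfig, seed: int) -> list[WeeklyRecord]:
    """Simulate the cage protocol and return one record per week.

    Weekly event order on the first day of each week: scheduled SSIMS
    addition, 24-hour reproduction-bottle lay, trap (with removal), fecundity
    assay on up to ten trapped wild-type females (returned after the vial
    days), then the census. Bottle broods eclose into the cage on their
    scheduled days; adult mortality and mating run daily.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    state = _CageState(cfg.tet)
    wm, wf = state.table.code(wt_male()), state.table.code(wt_female())
    sf, sm = state.table.code(ssims_female()), state.table.code(ssims_male())
    ssims_e = rearing_steady_state(cfg.rearing_tet, cfg.tet)

    n0 = cfg.initial_wild
    n_f = n0 // 2
    state.append(
        np.array([wf] * n_f + [wm] * (n0 - n_f)),
        np.zeros(n0),
        np.zeros(n0, np.int32),
    )

    pending_broods: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    returning: dict[int, list[tuple[int, float, int, int, np.ndarray]]] = {}
    records: list[WeeklyRecord] = []

    for week in range(1, cfg.weeks + 1):
        day0 = (week - 1) * 7
        # SSIMS addition at the start of the week
        if week in cfg.release_weeks and cfg.weekly_addition > 0:
            n = cfg.weekly_addition
            k_f = int(np.floor(n * cfg.addition_female_fraction))
            state.append(
                np.array([sf] * k_f + [sm] * (n - k_f)),
                np.full(n, ssims_e),
                np.zeros(n, np.int32),
            )
        trap_counts: dict[tuple[str, str], int] = {}
        fecundity_counts: list[int] = []
        for d in range(7):
            day = day0 + d
            for codes_j, exps_j, gens_j in pending_broods.pop(day, []):
                state.append(codes_j, exps_j, gens_j)
            for code_r, e_r, age_r, gen_r, row_r in returning.pop(day, []):
                # survival over the days away, then re-entry
                if rng.random() < (1.0 - cfg.adult_mortality) ** cfg.assay_absence_days:
                    state.append(
                        np.array([code_r]),
                        np.array([e_r]),
                        np.array([gen_r], np.int32),
                        age=np.array([age_r + cfg.assay_absence_days], np.int32),
                        sperm_rows=row_r[None, :],
                    )
            _daily_adults(state, cfg, rng)
            if d == 2:
                # reproduction bottle: 24 h lay, ecloses lag..lag+window-1
                # days later
                codes, exps, gens = _bottle_brood(state, cfg, rng)
                if codes.size:
                    share = rng.integers(0, cfg.emergence_window_days, size=codes.size)
                    for j in range(cfg.emergence_window_days):
                        sel = share == j
                        if sel.any():
                            dd = day + cfg.eclosion_lag_days + j
                            pending_broods.setdefault(dd, []).append(
                                (codes[sel], exps[sel], gens[sel])
                            )
            if d == 6:
                # trap with removal, then the fecundity assay
                rows = np.where(state.alive)[0]
                trapped = rows[rng.random(rows.size) < cfg.trap_probability]
                trap_counts = state.counts_by_class_sex(trapped)
                tab = state.table.arrays()
                wt_f = (
                    (tab["class_idx"][state.code[trapped]] == CLASS_LABELS.index("WT"))
                    & tab["female"][state.code[trapped]]
                )
                assay_rows = trapped[wt_f][: cfg.assay_females]
                for r in assay_rows:
                    store = tuple(
                        (state.table.genotypes[j], float(v))
                        for j, v in enumerate(state.sperm[r])
                        if v > 0
                    )
                    agent = Agent(
                        genotype=state.table.genotypes[int(state.code[r])],
                        tet_exposure=float(state.exposure[r]),
                        sperm_store=store,
                    )
                    fecundity_counts.append(
                        fecundity_assay(agent, rng, cfg.assay_fecundity_mean, cfg.tet)
                    )
                    returning.setdefault(day + cfg.assay_absence_days, []).append(
                        (
                            int(state.code[r]),
                            float(state.exposure[r]),
                            int(state.age[r]),
                            int(state.generation[r]),
                            state.sperm[r].copy(),
                        )
                    )
                state.alive[trapped] = False  # removal (assay females re-enter)
                state.compact()
        census = state.counts_by_class_sex(np.where(state.alive)[0])
        records.append(WeeklyRecord(week, trap_counts, fecundity_counts, census))
    return records
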