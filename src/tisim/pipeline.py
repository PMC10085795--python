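"""The three-phase trait-introgression program and campaign runner.

Phase 1 (initialization): donor x recurrent parent gives the F1 (t = 0),
which is backcrossed to the recurrent parent to give a segregating BC1F1
population (t = 1).  Phase 2 (selection): a selection strategy chooses
``NC(t)`` crosses at t = 2 and t = 3, each producing K progeny.  Phase 3
(selfing): from t = 4 on, the ``NC(t)`` individuals judged most likely to
yield successful selfed progeny are each selfed for 1,000 progeny until a
successful individual appears (the *successful generation*) or the deadline
passes (failure).

A *campaign* runs one program per (donor x strategy x resource level); the
per-program random seed derives from the root seed and the program key, so
results are independent of iteration order and reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .genetics_core import GeneticMap, Individual, Population, TraitArchitecture
from .meiosis import GameteModel, cross_progeny_haps, make_cross, sample_gametes_multi
from .strategy_bc import BgsBc, LasBc, LasConfig, PcvBc, SelectionContext
from .strategy_ic import BgsIc, LasIc, PcvIc

__all__ = [
    "RESOURCE_LEVELS",
    "STRATEGY_ORDER",
    "ResourcePlan",
    "ProgramRecord",
    "RunConfig",
    "make_strategy",
    "initialize",
    "run_selection_phase",
    "run_selfing_phase",
    "run_program",
    "run_campaign",
]

logger = logging.getLogger(__name__)

#: Crosses available per generation (t >= 2) at each named resource level.
RESOURCE_LEVELS = {"R1": 2, "R2": 3, "R3": 4, "R4": 5, "R5": 6}

STRATEGY_ORDER = ["bgs-bc", "pcv-bc", "las-bc", "bgs-ic", "pcv-ic", "las-ic"]


def make_strategy(name: str):
    factories = {
        "bgs-bc": BgsBc,
        "pcv-bc": PcvBc,
        "las-bc": LasBc,
        "bgs-ic": BgsIc,
        "pcv-ic": PcvIc,
        "las-ic": LasIc,
    }
    if name not in factories:
        raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGY_ORDER}")
    return factories[name]()


@dataclass
class ResourcePlan:
    """Cross budget per generation: one cross at t = 1, a flat NC afterwards."""

    name: str
    nc_per_generation: int

    def nc(self, t: int) -> int:
        return 1 if t <= 1 else self.nc_per_generation

    @classmethod
    def from_level(cls, level: str) -> "ResourcePlan":
        if level not in RESOURCE_LEVELS:
            raise ValueError(f"unknown resource level {level!r}")
        return cls(level, RESOURCE_LEVELS[level])


@dataclass
class RunConfig:
    """Program settings; defaults mirror the standard simulation setup."""

    K: int = 200
    reps: int = 1000
    rc_goal: float = 0.96
    deadline: int = 8
    las_deadline_T: int = 5
    npos: int = 5
    max_candidates: int = 10
    outer_cap: int = 10
    inner_cap: int = 6
    selfing_progeny: int = 1000
    refine_progeny: int = 200

    def las_config(self) -> LasConfig:
        return LasConfig(
            deadline_T=self.las_deadline_T,
            reps=self.reps,
            K=self.K,
            npos_cap=self.npos,
            max_candidates=self.max_candidates,
            outer_cap=self.outer_cap,
            inner_cap=self.inner_cap,
        )


@dataclass
class ProgramRecord:
    """Outcome of one donor's introgression program."""

    donor_id: str
    strategy: str
    level: str
    rc_goal: float
    deadline: int
    seed: int
    successful_generation: Optional[int] = None
    failure_reason: Optional[str] = None
    cross_fractions: Dict[int, Dict[str, float]] = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.successful_generation is None

    def to_dict(self) -> dict:
        return asdict(self)


class ProgramFailure(Exception):
    pass


def initialize(
    donor: Individual,
    rp: Individual,
    arch: TraitArchitecture,
    model: GameteModel,
    K: int,
    rng: np.random.Generator,
) -> Population:
    """F1 then BC1F1: the segregating population selection starts from (t = 1)."""
    if np.any(donor.dose()[arch.target_loci] == 0):
        raise ValueError(
            "donor lacks a favorable allele at a target locus; introgression impossible"
        )
    for who, ind in (("donor", donor), ("recurrent parent", rp)):
        if not ind.is_homozygous():
            warnings.warn(f"{who} is not fully inbred; F1 will segregate", stacklevel=2)
    f1 = make_cross(donor, rp, 1, model, rng, generation=0, rp_id=rp.id, id_prefix="F1").individual(0)
    f1.id = "F1"
    return make_cross(f1, rp, K, model, rng, generation=1, rp_id=rp.id, id_prefix="BC1F1")


def run_selection_phase(
    pop: Population,
    strategy,
    plan: ResourcePlan,
    ctx: SelectionContext,
    K: int,
) -> tuple:
    """Two generations of strategy-driven crossing (t = 2 and t = 3).

    Returns the t = 3 population and the per-generation cross-type fractions.
    """
    fractions: Dict[int, Dict[str, float]] = {}
    for t in (pop.generation + 1, pop.generation + 2):
        NC = plan.nc(t)
        cplan = strategy.select(pop, NC, ctx)
        if len(cplan) == 0:
            raise ProgramFailure(f"empty cross plan at t={t}")
        lookup = {pop.ids[i]: pop.haps[i] for i in range(len(pop))}
        lookup[ctx.rp.id] = ctx.rp.haplotypes
        haps_list, ids, pa, pb, ct = [], [], [], [], []
        for ci, (a, b, ctype) in enumerate(cplan.pairs):
            progeny = cross_progeny_haps(lookup[a], lookup[b], K, ctx.model, ctx.rng)
            haps_list.append(progeny)
            ids.extend(f"g{t}c{ci}_{k}" for k in range(K))
            pa.extend([a] * K)
            pb.extend([b] * K)
            ct.extend([ctype] * K)
        counts = {c: cplan.cross_types.count(c) for c in ("backcross", "intercross", "self")}
        fractions[t] = {c: counts[c] / len(cplan) for c in counts}
        pop = Population(
            np.concatenate(haps_list), ids, generation=t, parent_a=pa, parent_b=pb, cross_type=ct
        )
    return pop, fractions


def _selfing_scores(
    pop: Population,
    arch: TraitArchitecture,
    model: GameteModel,
    NC: int,
    refine_progeny: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Estimated probability that a selfed progeny of each individual is successful.

    Per-locus fixation odds (1, 1/4 or 0 for fixed-favorable, heterozygous,
    fixed-unfavorable target loci) times an indicator that the recovery-rate
    goal is attainable; candidates whose RC outcome is uncertain are refined
    with a small Monte Carlo selfing when they could be selected.
    """
    dose = pop.dose()
    tl, bg = arch.target_loci, arch.background_mask
    q = np.select([dose[:, tl] == 2, dose[:, tl] == 1], [1.0, 0.25], default=0.0)
    score = q.prod(axis=1)
    bgd = dose[:, bg]
    attainable = (bgd >= 1).mean(axis=1) >= arch.rc_goal
    score *= attainable
    floor_rc = (bgd == 2).mean(axis=1)
    uncertain = (score > 0) & (floor_rc < arch.rc_goal)
    if uncertain.any() and refine_progeny > 0:
        vb = pop.vb(arch)
        order = np.lexsort((-vb, -score))
        top = [i for i in order[: 3 * NC] if uncertain[i]]
        for i in top:
            ph = np.broadcast_to(pop.haps[i], (refine_progeny, *pop.haps[i].shape))
            g1 = sample_gametes_multi(ph, model, rng)
            g2 = sample_gametes_multi(ph, model, rng)
            sdose = g1.astype(np.int16) + g2.astype(np.int16)
            ok = (sdose[:, tl] == 2).all(axis=1)
            rc = sdose[:, bg].sum(axis=1) / (2.0 * bg.sum())
            score[i] = float((ok & (rc >= arch.rc_goal)).mean())
    return score


def run_selfing_phase(
    pop: Population,
    ctx: SelectionContext,
    plan: ResourcePlan,
    deadline: int,
    config: RunConfig,
):
    """Repeated selfing until a successful individual appears or time runs out.

    Returns the successful generation index, or raises ProgramFailure.
    """
    arch = ctx.arch
    for t in range(pop.generation + 1, deadline + 1):
        NC = plan.nc(t)
        scores = _selfing_scores(pop, arch, ctx.model, NC, config.refine_progeny, ctx.rng)
        if not (scores > 0).any():
            raise ProgramFailure(f"no viable selfing candidate at t={t}")
        vb = pop.vb(arch)
        order = np.lexsort((np.asarray(pop.ids), -vb, -scores))
        chosen = [i for i in order if scores[i] > 0][:NC]
        n_self = config.selfing_progeny
        haps_list, ids, pa = [], [], []
        for ci, i in enumerate(chosen):
            ph = np.broadcast_to(pop.haps[i], (n_self, *pop.haps[i].shape))
            g1 = sample_gametes_multi(ph, ctx.model, ctx.rng)
            g2 = sample_gametes_multi(ph, ctx.model, ctx.rng)
            haps_list.append(np.stack([g1, g2], axis=2))
            ids.extend(f"g{t}s{ci}_{k}" for k in range(n_self))
            pa.extend([pop.ids[i]] * n_self)
        pop = Population(
            np.concatenate(haps_list),
            ids,
            generation=t,
            parent_a=pa,
            parent_b=pa,
            cross_type=["self"] * len(ids),
        )
        if pop.successful_mask(arch).any():
            return t
    raise ProgramFailure(f"deadline ({deadline} generations) exceeded")


def run_program(
    donor: Individual,
    rp: Individual,
    strategy_name: str,
    level: str,
    arch: TraitArchitecture,
    gmap: GeneticMap,
    config: RunConfig,
    seed: int,
) -> ProgramRecord:
    """One donor's full introgression program; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    model = GameteModel(gmap.rf)
    plan = ResourcePlan.from_level(level)
    strategy = make_strategy(strategy_name)
    ctx = SelectionContext(rp=rp, arch=arch, model=model, rng=rng, las=config.las_config())
    record = ProgramRecord(
        donor_id=donor.id,
        strategy=strategy_name,
        level=level,
        rc_goal=arch.rc_goal,
        deadline=config.deadline,
        seed=seed,
    )
    try:
        pop = initialize(donor, rp, arch, model, config.K, rng)
        pop, fractions = run_selection_phase(pop, strategy, plan, ctx, config.K)
        record.cross_fractions = fractions
        record.successful_generation = run_selfing_phase(
            pop, ctx, plan, config.deadline, config
        )
    except ProgramFailure as exc:
        record.failure_reason = str(exc)
    return record


def program_seed(root_seed: int, donor_id: str, strategy_name: str, level: str) -> int:
    """Per-program seed derived from the program key, independent of run order."""
    strat_code = STRATEGY_ORDER.index(strategy_name)
    level_code = list(RESOURCE_LEVELS).index(level)
    donor_code = abs(hash_stable(donor_id)) % (2**31)
    ss = np.random.SeedSequence([int(root_seed), donor_code, strat_code, level_code])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def hash_stable(s: str) -> int:
    """Deterministic string hash (Python's hash() is salted per process)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def run_campaign(
    donors: Sequence[Individual],
    rp: Individual,
    strategies: Sequence[str],
    levels: Sequence[str],
    arch: TraitArchitecture,
    gmap: GeneticMap,
    config: RunConfig,
    root_seed: int,
    progress: bool = False,
) -> List[ProgramRecord]:
    """One program per (donor x strategy x level); failures are recorded, not raised."""
    records = []
    for strategy in strategies:
        for level in levels:
            for donor in donors:
                seed = program_seed(root_seed, donor.id, strategy, level)
                rec = run_program(donor, rp, strategy, level, arch, gmap, config, seed)
                records.append(rec)
                if progress:
                    logger.info(
                        "%s %s donor=%s -> %s",
                        strategy,
                        level,
                        donor.id,
                        rec.successful_generation or rec.failure_reason,
                    )
    return records
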