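"""Intercross-enabled selection strategies: BGS-IC, PCV-IC and LAS-IC.

These strategies may pair any two members of the current generation (or an
individual with itself, or with the recurrent parent), so a cross can cover
the target loci jointly even when neither parent is positive on its own.

* BGS-IC poses mate selection as an integer linear program: maximize, over
  selected pairs (i, j) with i <= j, the target-allele credit of member i
  (weighted by a constant ``W*`` exceeding any attainable background GEBV)
  plus the background GEBV of member j, subject to member i meeting the
  recovery-rate goal, joint coverage of every target locus, exactly ``NC``
  crosses, and single use of every individual except the recurrent parent.
* PCV-IC ranks pairs drawn from the recurrent parent plus the top-20%-GEBV
  individuals by predicted cross value.
* LAS-IC (the look-ahead intercrossing strategy) filters candidate pairs by
  target coverage, joint background potential and summed GEBV, then scores
  each surviving pair with a look-ahead Monte Carlo simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .genetics_core import Individual, Population, TraitArchitecture
from .lookahead import lookahead_ic_score
from .strategy_bc import CrossPlan, LasConfig, SelectionContext, pcv_many

__all__ = [
    "PairPool",
    "select_bgs_ic",
    "select_pcv_ic",
    "candidate_pair_filter",
    "las_ic_evaluate",
    "select_las_ic",
    "BgsIc",
    "PcvIc",
    "LasIc",
]

logger = logging.getLogger(__name__)


def _entities(pop: Population, ctx: SelectionContext, rp_first: bool):
    """Stack population and recurrent parent into one array block."""
    rp_h = ctx.rp.haplotypes[None]
    if rp_first:
        haps = np.concatenate([rp_h, pop.haps])
        ids = [ctx.rp.id] + list(pop.ids)
        rp_idx = 0
    else:
        haps = np.concatenate([pop.haps, rp_h])
        ids = list(pop.ids) + [ctx.rp.id]
        rp_idx = len(pop)
    return haps, ids, rp_idx


def _pair_type(i: int, j: int, rp_idx: int) -> str:
    if i == j:
        return "self"
    if rp_idx in (i, j):
        return "backcross"
    return "intercross"


def _stats(haps: np.ndarray, arch: TraitArchitecture):
    dose = haps.sum(axis=2, dtype=np.int16)
    bg = arch.background_mask
    rc = dose[:, bg].sum(axis=1) / (2.0 * bg.sum())
    vb = dose[:, bg] @ arch.background_effects
    tdose = dose[:, arch.target_loci]
    return dose, rc, vb, tdose


# -- BGS-IC: integer programming ----------------------------------------------


def select_bgs_ic(
    pop: Population,
    NC: int,
    ctx: SelectionContext,
    symmetric_rc: bool = False,
    wstar: Optional[float] = None,
) -> CrossPlan:
    """Mate selection by the BGS integer linear program.

    Pairs (i, j), i <= j, over the recurrent parent (index 0) and the
    population.  The objective credits member i with ``W*`` per favorable
    target allele and member j with its background GEBV; member i must meet
    the recovery-rate goal (both members if ``symmetric_rc``), the pair must
    jointly cover every target locus, exactly ``NC`` pairs are chosen, and
    each non-RP individual is used at most once on either side of a pair.
    Infeasible instances relax in stages: first the cross count, then the
    recovery-rate threshold (to the best attainable), both logged.
    """
    haps, ids, rp_idx = _entities(pop, ctx, rp_first=True)
    _, rc, vb, tdose = _stats(haps, ctx.arch)
    n = len(ids)
    if wstar is None:
        wstar = ctx.arch.max_background_gebv + 1.0
    elif wstar <= ctx.arch.max_background_gebv:
        raise ValueError("W* must exceed twice the summed background effects")
    tcount = tdose.sum(axis=1).astype(float)  # W* credit counts favorable target alleles
    uncov = np.zeros(n, dtype=np.int64)
    for k in range(ctx.arch.n_targets):
        uncov |= (tdose[:, k] == 0).astype(np.int64) << k

    def build_vars(goal: float):
        iis, jjs, coef = [], [], []
        ok_i = rc >= goal
        for i in range(n):
            if not ok_i[i]:
                continue
            js = np.arange(i, n)
            cov = (uncov[i] & uncov[i:]) == 0
            if symmetric_rc:
                cov &= rc[i:] >= goal
            for j in js[cov]:
                iis.append(i)
                jjs.append(int(j))
                coef.append(wstar * tcount[i] + vb[int(j)])
        return np.array(iis), np.array(jjs), np.array(coef)

    def solve(goal: float, nc: int):
        iis, jjs, coef = build_vars(goal)
        nv = len(coef)
        if nv == 0:
            return None
        rows, cols = [], []
        # one row per non-RP index, counting appearances as i; one as j
        for v in range(nv):
            if iis[v] != rp_idx:
                rows.append(iis[v])
                cols.append(v)
            if jjs[v] != rp_idx:
                rows.append(n + jjs[v])
                cols.append(v)
        cons = [LinearConstraint(np.ones((1, nv)), nc, nc)]
        if rows:
            A = sparse.coo_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(2 * n, nv)
            ).tocsr()
            keep = np.asarray(A.sum(axis=1)).ravel() > 0
            cons.append(LinearConstraint(A[keep], -np.inf, 1))
        res = milp(
            c=-coef,
            constraints=cons,
            integrality=np.ones(nv),
            bounds=Bounds(0, 1),
        )
        if res.status != 0:
            return None
        sel = np.flatnonzero(np.round(res.x) > 0.5)
        return [(int(iis[v]), int(jjs[v])) for v in sel]

    max_rc = float(rc[1:].max()) if n > 1 else 0.0
    goals = [ctx.arch.rc_goal]
    if max_rc < ctx.arch.rc_goal:
        goals.append(max_rc)  # stage-2 relaxation: best attainable RC
    for goal in goals:
        for nc in range(NC, 0, -1):
            chosen = solve(goal, nc)
            if chosen is not None:
                if nc < NC or goal != ctx.arch.rc_goal:
                    logger.warning(
                        "BGS-IC relaxed: NC %d -> %d, rc threshold %.4f", NC, nc, goal
                    )
                pairs = [
                    (ids[i], ids[j], _pair_type(i, j, rp_idx)) for i, j in chosen
                ]
                return CrossPlan(pairs)
    logger.warning("BGS-IC found no feasible cross at all")
    return CrossPlan([])


# -- PCV-IC --------------------------------------------------------------------


def select_pcv_ic(
    pop: Population,
    NC: int,
    ctx: SelectionContext,
    top_frac: float = 0.2,
) -> CrossPlan:
    """Predicted-cross-value mate selection over a GEBV-prescreened pool.

    Candidates are the recurrent parent plus the top ``top_frac`` of the
    population by background GEBV; all unordered pairs (including selfs)
    that jointly cover the target loci are ranked by PCV and the best ``NC``
    are taken with every non-RP individual used at most once.
    """
    haps, ids, rp_idx = _entities(pop, ctx, rp_first=False)
    _, rc, vb, tdose = _stats(haps, ctx.arch)
    n = len(pop)
    k = max(1, int(round(top_frac * n)))
    order = sorted(range(n), key=lambda i: (-vb[i], ids[i]))
    cand = sorted(order[:k]) + [rp_idx]
    uncov = np.zeros(len(ids), dtype=np.int64)
    for t in range(ctx.arch.n_targets):
        uncov |= (tdose[:, t] == 0).astype(np.int64) << t
    pairs = [
        (i, j)
        for ai, i in enumerate(cand)
        for j in cand[ai:]
        if (uncov[i] & uncov[j]) == 0
    ]
    if not pairs:
        logger.warning("PCV-IC: no pair covers the target loci")
        return CrossPlan([])
    pa = np.stack([haps[i] for i, _ in pairs])
    pb = np.stack([haps[j] for _, j in pairs])
    scores = pcv_many(pa, pb, ctx.model.rf)
    ranked = sorted(
        range(len(pairs)),
        key=lambda q: (-scores[q], -(vb[pairs[q][0]] + vb[pairs[q][1]]), pairs[q]),
    )
    plan: List[Tuple[str, str, str]] = []
    used: set = set()
    for q in ranked:
        if len(plan) == NC:
            break
        i, j = pairs[q]
        members = {m for m in (i, j) if m != rp_idx}
        if members & used:
            continue
        used |= members
        plan.append((ids[i], ids[j], _pair_type(i, j, rp_idx)))
    if len(plan) < NC:
        logger.warning("PCV-IC: only %d of %d crosses available", len(plan), NC)
    return CrossPlan(plan)


# -- LAS-IC --------------------------------------------------------------------


@dataclass
class PairPool:
    """Candidate pairs surviving the filter, sorted by summed background GEBV."""

    ids: List[str]
    haps: np.ndarray  # (n_entities, P, 2): population then recurrent parent
    rp_index: int
    pairs: np.ndarray  # (k, 2) entity indices, i <= j
    vb_sum: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def candidate_pair_filter(
    pop: Population,
    ctx: SelectionContext,
    fraction: float,
    cap: Optional[int] = None,
) -> PairPool:
    """Filter all unordered pairs (including selfs and RP pairs) down to a pool.

    Criteria: full genetic potential at the target loci; joint background
    genetic potential strictly above the recovery-rate goal; rank by summed
    background GEBV and keep the top ``max(1, round(fraction * N))`` pairs
    (N = population size), further bounded by ``cap``.  If no pair meets
    both criteria the coverage-only pairs are used as a fallback.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    haps, ids, rp_idx = _entities(pop, ctx, rp_first=False)
    dose, rc, vb, tdose = _stats(haps, ctx.arch)
    m = len(ids)
    uncov = np.zeros(m, dtype=np.int64)
    for t in range(ctx.arch.n_targets):
        uncov |= (tdose[:, t] == 0).astype(np.int64) << t
    cov = (uncov[:, None] & uncov[None, :]) == 0
    bgmask = ctx.arch.background_mask
    z = (dose[:, bgmask] == 0).astype(np.float32)
    gp_bl = 1.0 - (z @ z.T) / bgmask.sum()
    triu = np.triu(np.ones((m, m), dtype=bool))
    elig = cov & (gp_bl > ctx.arch.rc_goal) & triu
    if not elig.any():
        logger.warning("pair filter: no pair passes both criteria; coverage-only fallback")
        elig = cov & triu
        if not elig.any():
            return PairPool(ids, haps, rp_idx, np.empty((0, 2), dtype=int), np.empty(0))
    size = max(1, int(round(fraction * len(pop))))
    if cap is not None:
        size = min(size, cap)
    ii, jj = np.nonzero(elig)
    vbsum = vb[ii] + vb[jj]
    order = sorted(range(len(ii)), key=lambda q: (-vbsum[q], ii[q], jj[q]))
    take = order[: min(size, len(order))]
    return PairPool(
        ids,
        haps,
        rp_idx,
        np.stack([ii[take], jj[take]], axis=1),
        vbsum[take],
    )


def las_ic_evaluate(
    p1: Individual,
    p2: Individual,
    cfg: LasConfig,
    ctx: SelectionContext,
    t: int,
    pop_size: int,
) -> float:
    """Look-ahead Monte Carlo score of one candidate pair at generation ``t``.

    ``pop_size`` is the real current-generation size N, which fixes the
    inner filter's pool at ``round(inner_frac * N)`` (bounded by the cap).
    """
    n_inner = max(cfg.deadline_T - 1 - (t + 1), 0)
    inner_size = max(1, int(round(cfg.inner_frac * pop_size)))
    inner_size = min(inner_size, cfg.inner_cap)
    return lookahead_ic_score(
        p1.haplotypes,
        p2.haplotypes,
        ctx.rp.haplotypes,
        ctx.arch,
        ctx.model,
        reps=cfg.reps,
        K=cfg.K,
        npos=cfg.npos_cap,
        n_inner=n_inner,
        inner_pool_size=inner_size,
        rng=ctx.rng,
    )


def select_las_ic(pop: Population, NC: int, ctx: SelectionContext) -> CrossPlan:
    """Look-ahead intercrossing selection.

    Builds the outer candidate-pair pool, scores every pair by look-ahead
    simulation and keeps the best ``NC``; the same individual may appear in
    several selected pairs, and reciprocal duplicates cannot occur because
    pairs are unordered.
    """
    cfg = ctx.las
    pool = candidate_pair_filter(pop, ctx, cfg.outer_frac, cap=cfg.outer_cap)
    if len(pool) == 0:
        return CrossPlan([])
    scores = np.empty(len(pool))
    for q, (i, j) in enumerate(pool.pairs):
        scores[q] = lookahead_ic_score(
            pool.haps[i],
            pool.haps[j],
            ctx.rp.haplotypes,
            ctx.arch,
            ctx.model,
            reps=cfg.reps,
            K=cfg.K,
            npos=cfg.npos_cap,
            n_inner=max(cfg.deadline_T - 1 - (pop.generation + 1), 0),
            inner_pool_size=min(
                max(1, int(round(cfg.inner_frac * len(pop)))), cfg.inner_cap
            ),
            rng=ctx.rng,
        )
    ranked = sorted(
        range(len(pool)),
        key=lambda q: (-scores[q], -pool.vb_sum[q], tuple(pool.pairs[q])),
    )
    if len(pool) < NC:
        logger.warning("LAS-IC pool smaller than NC (%d < %d)", len(pool), NC)
    plan = [
        (
            pool.ids[pool.pairs[q][0]],
            pool.ids[pool.pairs[q][1]],
            _pair_type(pool.pairs[q][0], pool.pairs[q][1], pool.rp_index),
        )
        for q in ranked[:NC]
    ]
    return CrossPlan(plan)


# -- strategy objects ----------------------------------------------------------


class BgsIc:
    name = "bgs-ic"

    def __init__(self, symmetric_rc: bool = False):
        self.symmetric_rc = symmetric_rc

    def select(self, pop, NC, ctx):
        return select_bgs_ic(pop, NC, ctx, symmetric_rc=self.symmetric_rc)


class PcvIc:
    name = "pcv-ic"

    def __init__(self, top_frac: float = 0.2):
        self.top_frac = top_frac

    def select(self, pop, NC, ctx):
        return select_pcv_ic(pop, NC, ctx, top_frac=self.top_frac)


class LasIc:
    name = "las-ic"

    def select(self, pop, NC, ctx):
        return select_las_ic(pop, NC, ctx)
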