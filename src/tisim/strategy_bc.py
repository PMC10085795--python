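"""Backcross-only selection strategies: BGS-BC, PCV-BC and LAS-BC.

All three strategies rank the *positive* individuals of the current
generation (those carrying at least one favorable allele at every target
locus) and pair the top ``NC`` of them with the recurrent parent:

* BGS-BC ranks by background GEBV ``VB`` — the effect-weighted favorable
  background allele count of the candidate itself;
* PCV-BC ranks by the predicted cross value — the exact probability that a
  random gamete of a random progeny of candidate x recurrent parent carries
  the favorable allele at every locus;
* LAS-BC ranks by a look-ahead Monte Carlo estimate of the expected
  performance of the selfed population at the program deadline.

Ties are broken by (score desc, VB desc, id asc) for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genetics_core import Individual, Population, TraitArchitecture
from .lookahead import lookahead_bc_score
from .meiosis import GameteModel

__all__ = [
    "CrossPlan",
    "LasConfig",
    "SelectionContext",
    "pcv",
    "pcv_many",
    "select_bgs_bc",
    "select_pcv_bc",
    "las_evaluate_bc",
    "select_las_bc",
    "BgsBc",
    "PcvBc",
    "LasBc",
]

logger = logging.getLogger(__name__)


@dataclass
class CrossPlan:
    """A selected set of parent pairs with cross types for one generation."""

    pairs: List[Tuple[str, str, str]]  # (parent_a id, parent_b id, cross_type)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def cross_types(self) -> List[str]:
        return [t for _, _, t in self.pairs]


@dataclass
class LasConfig:
    """Monte Carlo look-ahead settings.

    ``deadline_T`` is the generation the look-ahead targets (intermediate
    crossing stops at ``T - 1``, which is then selfed); ``reps`` repetitions
    of ``K``-progeny crosses are averaged.  ``npos_cap`` bounds how many
    positive individuals are selfed in the terminal step, and
    ``max_candidates`` / ``outer_cap`` / ``inner_cap`` bound how many
    candidates (individuals or filtered pairs) are evaluated per selection —
    computational budgets, applied after the 0.1N / 0.05N pool-size rules.
    """

    deadline_T: int = 5
    reps: int = 1000
    K: int = 200
    npos_cap: int = 5
    max_candidates: int = 10
    outer_frac: float = 0.1
    inner_frac: float = 0.05
    outer_cap: int = 10
    inner_cap: int = 6


@dataclass
class SelectionContext:
    """Everything a strategy needs besides the population itself."""

    rp: Individual
    arch: TraitArchitecture
    model: GameteModel
    rng: np.random.Generator
    las: LasConfig = field(default_factory=LasConfig)


# -- predicted cross value -----------------------------------------------------


def pcv_many(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    rf: np.ndarray,
    loci: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Predicted cross value for a batch of parent pairs.

    Exact transfer-matrix dynamic program over loci with an 8-state source
    vector: (which progeny gamete the final gamete copies from) x (source
    haplotype inside each parent's meiosis).  Each of the three meioses
    switches source independently with probability ``rf[p-1]`` between
    consecutive loci; a state survives locus ``p`` only if its implied
    allele is favorable (for ``p`` in ``loci``; default all loci).

    ``haps_a``/``haps_b`` have shape ``(B, P, 2)``; returns ``(B,)``.
    """
    A = np.asarray(haps_a, dtype=np.float64)
    Bh = np.asarray(haps_b, dtype=np.float64)
    if A.shape != Bh.shape or A.ndim != 3:
        raise ValueError("haps_a and haps_b must both be (B, P, 2)")
    B, P, _ = A.shape
    rf = np.asarray(rf, dtype=float)
    if len(rf) != P - 1:
        raise ValueError("rf must have length P - 1")
    use = np.zeros(P, dtype=bool)
    use[np.arange(P) if loci is None else np.asarray(list(loci), dtype=int)] = True
    # mass over states (progeny source, meiosis-A source, meiosis-B source)
    m = np.full((B, 2, 2, 2), 0.125)
    for p in range(P):
        if p > 0:
            r = rf[p - 1]
            for ax in (1, 2, 3):
                m = (1.0 - r) * m + r * np.flip(m, axis=ax)
        if use[p]:
            m[:, 0, :, :] *= A[:, p, :, None]
            m[:, 1, :, :] *= Bh[:, p, None, :]
    return m.reshape(B, -1).sum(axis=1)


def pcv(
    p1: Individual,
    p2: Individual,
    rf: np.ndarray,
    loci: Optional[Sequence[int]] = None,
) -> float:
    """Probability that a random gamete of a random progeny of ``p1 x p2``
    carries the favorable allele at every locus in ``loci`` (default: all)."""
    return float(pcv_many(p1.haplotypes[None], p2.haplotypes[None], rf, loci)[0])


# -- selection -----------------------------------------------------------------


def _ranked_backcross_plan(
    pop: Population,
    NC: int,
    ctx: SelectionContext,
    scores: np.ndarray,
    pos_idx: np.ndarray,
) -> CrossPlan:
    """Top-NC positive candidates paired with the RP, stable tie-breaking."""
    vb = pop.vb(ctx.arch)[pos_idx]
    ids = [pop.ids[i] for i in pos_idx]
    order = sorted(range(len(pos_idx)), key=lambda k: (-scores[k], -vb[k], ids[k]))
    if len(order) < NC:
        logger.warning(
            "only %d positive candidates for %d crosses; plan shrinks", len(order), NC
        )
    chosen = order[:NC]
    return CrossPlan([(ids[k], ctx.rp.id, "backcross") for k in chosen])


def _positives(pop: Population, ctx: SelectionContext) -> np.ndarray:
    return np.flatnonzero(pop.positive_mask(ctx.arch))


def select_bgs_bc(pop: Population, NC: int, ctx: SelectionContext) -> CrossPlan:
    """Background selection: highest-VB positives crossed to the RP."""
    pos_idx = _positives(pop, ctx)
    if pos_idx.size == 0:
        return CrossPlan([])
    scores = pop.vb(ctx.arch)[pos_idx]
    return _ranked_backcross_plan(pop, NC, ctx, scores, pos_idx)


def select_pcv_bc(pop: Population, NC: int, ctx: SelectionContext) -> CrossPlan:
    """Predicted-cross-value selection against the recurrent parent."""
    pos_idx = _positives(pop, ctx)
    if pos_idx.size == 0:
        return CrossPlan([])
    haps_a = pop.haps[pos_idx]
    haps_b = np.broadcast_to(ctx.rp.haplotypes, haps_a.shape)
    scores = pcv_many(haps_a, haps_b, ctx.model.rf)
    return _ranked_backcross_plan(pop, NC, ctx, scores, pos_idx)


def las_evaluate_bc(ind: Individual, cfg: LasConfig, ctx: SelectionContext, t: int) -> float:
    """Look-ahead Monte Carlo score of one positive candidate at generation t.

    Simulates repeated backcrossing of the candidate to the recurrent
    parent through generation ``T - 1`` followed by selfing, and returns the
    mean expected selfed-cohort performance V over ``cfg.reps`` repetitions.
    """
    n_crosses = max(cfg.deadline_T - 1 - t, 1)
    return lookahead_bc_score(
        ind.haplotypes,
        ctx.rp.haplotypes,
        ctx.arch,
        ctx.model,
        reps=cfg.reps,
        K=cfg.K,
        npos=cfg.npos_cap,
        n_crosses=n_crosses,
        rng=ctx.rng,
    )


def select_las_bc(pop: Population, NC: int, ctx: SelectionContext) -> CrossPlan:
    """Look-ahead selection: candidates with best simulated future performance."""
    cfg = ctx.las
    pos_idx = _positives(pop, ctx)
    if pos_idx.size == 0:
        return CrossPlan([])
    vb = pop.vb(ctx.arch)
    # evaluate at most max_candidates candidates, prescreened by VB
    if pos_idx.size > cfg.max_candidates:
        order = sorted(pos_idx, key=lambda i: (-vb[i], pop.ids[i]))
        pos_idx = np.asarray(order[: cfg.max_candidates])
    scores = np.array(
        [las_evaluate_bc(pop.individual(i), cfg, ctx, pop.generation) for i in pos_idx]
    )
    return _ranked_backcross_plan(pop, NC, ctx, scores, pos_idx)


# -- strategy objects ----------------------------------------------------------


class _Strategy:
    name: str = ""

    def select(self, pop: Population, NC: int, ctx: SelectionContext) -> CrossPlan:
        raise NotImplementedError


class BgsBc(_Strategy):
    name = "bgs-bc"

    def select(self, pop, NC, ctx):
        return select_bgs_bc(pop, NC, ctx)


class PcvBc(_Strategy):
    name = "pcv-bc"

    def select(self, pop, NC, ctx):
        return select_pcv_bc(pop, NC, ctx)


class LasBc(_Strategy):
    name = "las-bc"

    def select(self, pop, NC, ctx):
        return select_las_bc(pop, NC, ctx)
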