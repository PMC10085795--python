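"""Backcross strategies: exact predicted cross value, GEBV ranking, and the
look-ahead Monte Carlo evaluator."""

import itertools

import numpy as np
import pytest

from tisim.genetics_core import Individual, Population
from tisim.meiosis import GameteModel, enumerate_gamete_distribution
from tisim.strategy_bc import (
    LasConfig,
    SelectionContext,
    las_evaluate_bc,
    pcv,
    pcv_many,
    select_bgs_bc,
    select_las_bc,
    select_pcv_bc,
)

from conftest import simple_arch


def pcv_brute(h_a, h_b, rf):
    """Two-meiosis enumeration: random progeny of a x b, then a random
    gamete of that progeny; probability it is favorable at every locus."""
    da = enumerate_gamete_distribution(Individual("a", h_a), rf)
    db = enumerate_gamete_distribution(Individual("b", h_b), rf)
    total = 0.0
    for ga, p_ga in da:
        for gb, p_gb in db:
            progeny = np.stack([ga, gb], axis=1).astype(np.uint8)
            for g, p in enumerate_gamete_distribution(Individual("p", progeny), rf):
                if all(g):
                    total += p_ga * p_gb * p
    return total


class TestPcv:
    def test_both_parents_fully_favorable(self):
        h = np.ones((4, 2), dtype=np.uint8)
        assert pcv(Individual("a", h), Individual("b", h), np.full(3, 0.2)) == pytest.approx(1.0)

    def test_single_locus_enumeration_cases(self):
        het = Individual("het", np.array([[1, 0]], dtype=np.uint8))
        hom0 = Individual("h0", np.array([[0, 0]], dtype=np.uint8))
        rf = np.empty(0)
        assert pcv(het, hom0, rf) == pytest.approx(0.25)
        assert pcv(het, het, rf) == pytest.approx(0.5)

    def test_matches_two_meiosis_enumeration(self, rng):
        """Exact DP equals brute-force enumeration on random small instances."""
        worst = 0.0
        for _ in range(60):
            P = int(rng.integers(2, 7))
            ha = rng.integers(0, 2, (P, 2), dtype=np.uint8)
            hb = rng.integers(0, 2, (P, 2), dtype=np.uint8)
            rf = np.clip(rng.random(P - 1) * 0.5, 1e-6, 0.5)
            got = pcv_many(ha[None], hb[None], rf)[0]
            worst = max(worst, abs(got - pcv_brute(ha, hb, rf)))
        assert worst < 1e-10

    def test_symmetry_and_self_consistency(self, rng):
        P = 5
        ha = rng.integers(0, 2, (P, 2), dtype=np.uint8)
        hb = rng.integers(0, 2, (P, 2), dtype=np.uint8)
        rf = np.clip(rng.random(P - 1) * 0.5, 1e-6, 0.5)
        a, b = Individual("a", ha), Individual("b", hb)
        assert pcv(a, b, rf) == pytest.approx(pcv(b, a, rf), abs=1e-14)
        assert pcv(a, a, rf) == pytest.approx(pcv_brute(ha, ha, rf), abs=1e-10)

    def test_monotone_in_favorable_alleles(self, rng):
        """Flipping any 0 allele to 1 in either parent never decreases PCV."""
        P = 4
        rf = np.full(P - 1, 0.3)
        ha = rng.integers(0, 2, (P, 2), dtype=np.uint8)
        hb = rng.integers(0, 2, (P, 2), dtype=np.uint8)
        base = pcv_many(ha[None], hb[None], rf)[0]
        for h in (ha, hb):
            for p, m in itertools.product(range(P), range(2)):
                if h[p, m] == 0:
                    h2 = h.copy()
                    h2[p, m] = 1
                    pair = (h2, hb) if h is ha else (ha, h2)
                    assert pcv_many(pair[0][None], pair[1][None], rf)[0] >= base - 1e-12

    def test_subset_loci_argument(self):
        # restricting to a subset only constrains those loci
        ha = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        hb = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        rf = np.array([0.3])
        assert pcv_many(ha[None], hb[None], rf, loci=[0])[0] == pytest.approx(1.0)
        assert pcv_many(ha[None], hb[None], rf)[0] == pytest.approx(0.0)


def _bc_context(P, targets, rc_goal=0.5, seed=0, rf_val=0.2, **las):
    rp_h = np.ones((P, 2), dtype=np.uint8)
    rp_h[list(targets)] = 0
    rp = Individual("RP", rp_h)
    arch = simple_arch(P, targets, rc_goal=rc_goal)
    model = GameteModel(np.full(P - 1, rf_val))
    return SelectionContext(
        rp=rp, arch=arch, model=model, rng=np.random.default_rng(seed),
        las=LasConfig(**las) if las else LasConfig(),
    )


def pop_from_doses(rows, generation=1):
    haps = []
    for d in rows:
        d = np.asarray(d)
        h = np.zeros((len(d), 2), dtype=np.uint8)
        h[d >= 1, 0] = 1
        h[d == 2, 1] = 1
        haps.append(h)
    return Population(np.stack(haps), [f"i{k}" for k in range(len(rows))], generation=generation)


class TestSelectBgsBc:
    def test_single_positive_candidate(self):
        ctx = _bc_context(4, [1])
        pop = pop_from_doses([[2, 1, 0, 0], [2, 0, 2, 2]])
        plan = select_bgs_bc(pop, 1, ctx)
        assert plan.pairs == [("i0", "RP", "backcross")]

    def test_ranking_by_vb(self):
        ctx = _bc_context(5, [0])
        # VB = 7, 9, 3 among positives
        pop = pop_from_doses([[1, 2, 2, 2, 1], [1, 2, 2, 2, 2], [1, 2, 1, 0, 0]])
        plan = select_bgs_bc(pop, 2, ctx)
        assert [p[0] for p in plan.pairs] == ["i1", "i0"]

    def test_selected_set_maximizes_total_vb(self, rng):
        """Exhaustive check: the chosen NC-subset attains the maximal VB sum."""
        ctx = _bc_context(6, [2])
        rows = rng.integers(0, 3, (9, 6))
        rows[:, 2] = rng.integers(1, 3, 9)  # keep everyone positive
        pop = pop_from_doses(rows)
        NC = 3
        plan = select_bgs_bc(pop, NC, ctx)
        vb = pop.vb(ctx.arch)
        best = max(sum(c) for c in itertools.combinations(vb, NC))
        chosen = sum(vb[pop.ids.index(a)] for a, _, _ in plan.pairs)
        assert chosen == pytest.approx(best)

    def test_plan_shrinks_when_positives_scarce(self, caplog):
        ctx = _bc_context(4, [1])
        pop = pop_from_doses([[2, 1, 0, 0], [2, 0, 2, 2]])
        plan = select_bgs_bc(pop, 3, ctx)
        assert len(plan) == 1


class TestSelectPcvBc:
    def test_tight_coupling_ranks_higher(self):
        """A favorable background allele linked closer to the target beats a
        distant one (hand-checkable 3-locus comparison)."""
        ctx = _bc_context(3, [1], rf_val=0.05)
        # candidate 0: favorable bg allele adjacent to target on same gamete;
        # candidate 1: same count but unfavorable right next to target
        h0 = np.array([[1, 0], [1, 0], [0, 0]], dtype=np.uint8)
        h1 = np.array([[0, 0], [1, 0], [1, 1]], dtype=np.uint8)
        pop = Population(np.stack([h0, h1]), ["coupled", "distal"], generation=1)
        rf = np.array([0.05, 0.4])
        ctx.model = GameteModel(rf)
        scores = pcv_many(pop.haps, np.broadcast_to(ctx.rp.haplotypes, pop.haps.shape), rf)
        plan = select_pcv_bc(pop, 1, ctx)
        assert plan.pairs[0][0] == pop.ids[int(np.argmax(scores))]

    def test_ranking_matches_brute_force(self, rng):
        P = 5
        ctx = _bc_context(P, [2], rf_val=0.2)
        rows = rng.integers(0, 3, (6, P))
        rows[:, 2] = rng.integers(1, 3, 6)
        pop = pop_from_doses(rows)
        rf = ctx.model.rf
        brute = [
            pcv_brute(pop.haps[i], ctx.rp.haplotypes, rf) for i in range(len(pop))
        ]
        order = np.argsort([-b for b in brute], kind="stable")
        plan = select_pcv_bc(pop, 2, ctx)
        assert {p[0] for p in plan.pairs} == {pop.ids[i] for i in order[:2]}


class TestLasEvaluateBc:
    def test_fixed_seed_reproducible(self):
        ctx = _bc_context(6, [2], seed=3, reps=2, K=30, deadline_T=5)
        cand = pop_from_doses([[2, 2, 1, 1, 2, 2]]).individual(0)
        a = las_evaluate_bc(cand, ctx.las, ctx, t=1)
        ctx2 = _bc_context(6, [2], seed=3, reps=2, K=30, deadline_T=5)
        b = las_evaluate_bc(cand, ctx2.las, ctx2, t=1)
        assert a == b

    def test_near_deterministic_ideal_candidate(self):
        """An ideal candidate (fixed targets, RP background) backcrossed once
        gives target-heterozygous progeny with perfect background, so each
        selfed progeny succeeds with probability 1/4 per target locus and the
        score approaches max-VB / 4 (one target locus here)."""
        ctx = _bc_context(5, [2], rc_goal=0.9, seed=1, reps=200, K=60)
        ideal = pop_from_doses([[2, 2, 2, 2, 2]]).individual(0)
        score = las_evaluate_bc(ideal, ctx.las, ctx, t=3)
        assert score == pytest.approx(ctx.arch.max_background_gebv / 4, rel=0.05)

    def test_score_nonincreasing_in_rc_goal(self):
        """Raising the recovery-rate goal shrinks the success set."""
        scores = []
        for rc_goal in (0.5, 0.8, 0.95):
            ctx = _bc_context(8, [3], rc_goal=rc_goal, seed=11, reps=60, K=60)
            cand = pop_from_doses([[2, 1, 2, 1, 1, 2, 0, 1]]).individual(0)
            scores.append(las_evaluate_bc(cand, ctx.las, ctx, t=2))
        assert scores[0] >= scores[1] >= scores[2]


class TestSelectLasBc:
    def test_dominant_candidate_selected(self):
        """Short look-ahead horizon: the candidate with fixed targets and a
        perfect background beats a bare-target candidate."""
        ctx = _bc_context(5, [2], rc_goal=0.9, seed=5, reps=40, K=40)
        pop = pop_from_doses([[2, 2, 2, 2, 2], [0, 0, 1, 0, 0]], generation=3)
        plan = select_las_bc(pop, 1, ctx)
        assert plan.pairs[0][0] == "i0"

    def test_matched_seed_plan_deterministic(self):
        for _ in range(2):
            plans = []
            for _ in range(2):
                ctx = _bc_context(6, [1], seed=9, reps=3, K=25)
                pop = pop_from_doses([[1, 2, 2, 1, 0, 2], [0, 1, 1, 2, 2, 2], [2, 1, 0, 2, 2, 1]])
                plans.append(select_las_bc(pop, 2, ctx).pairs)
            assert plans[0] == plans[1]
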