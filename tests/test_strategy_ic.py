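"""Intercross strategies: the mate-selection ILP against exhaustive
enumeration, the PCV pair ranking, the candidate-pair filter, and the
look-ahead pair evaluator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tisim.genetics_core import Individual, Population
from tisim.meiosis import GameteModel
from tisim.strategy_bc import LasConfig, SelectionContext
from tisim.strategy_ic import (
    candidate_pair_filter,
    las_ic_evaluate,
    select_bgs_ic,
    select_las_ic,
    select_pcv_ic,
)

from conftest import simple_arch
from test_strategy_bc import pop_from_doses


def make_ctx(P, targets, rc_goal=0.5, seed=0, rf_val=0.2, effects=None, **las):
    rp_h = np.ones((P, 2), dtype=np.uint8)
    rp_h[list(targets)] = 0
    rp = Individual("RP", rp_h)
    arch = simple_arch(P, targets, rc_goal=rc_goal, effects=effects)
    return SelectionContext(
        rp=rp,
        arch=arch,
        model=GameteModel(np.full(P - 1, rf_val)),
        rng=np.random.default_rng(seed),
        las=LasConfig(**las) if las else LasConfig(),
    )


def ilp_brute_force(pop, NC, ctx):
    """Exhaustive enumeration of the mate-selection program's feasible
    solutions (written independently from the solver path)."""
    arch = ctx.arch
    haps = np.concatenate([ctx.rp.haplotypes[None], pop.haps])
    n = len(haps)
    dose = haps.sum(2)
    bgmask = arch.background_mask
    rc = dose[:, bgmask].sum(1) / (2 * bgmask.sum())
    vb = dose[:, bgmask] @ arch.background_effects
    tcount = dose[:, arch.target_loci].sum(1)
    wstar = arch.max_background_gebv + 1
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if rc[i] >= arch.rc_goal
        and np.all(dose[i, arch.target_loci] + dose[j, arch.target_loci] >= 1)
    ]
    best = None
    for combo in itertools.combinations(range(len(pairs)), NC):
        used_i, used_j, ok = set(), set(), True
        for q in combo:
            i, j = pairs[q]
            if i != 0:
                if i in used_i:
                    ok = False
                    break
                used_i.add(i)
            if j != 0:
                if j in used_j:
                    ok = False
                    break
                used_j.add(j)
        if not ok:
            continue
        obj = sum(wstar * tcount[pairs[q][0]] + vb[pairs[q][1]] for q in combo)
        if best is None or obj > best:
            best = obj
    return best


def plan_objective(plan, pop, ctx):
    arch = ctx.arch
    haps = np.concatenate([ctx.rp.haplotypes[None], pop.haps])
    ids = [ctx.rp.id] + list(pop.ids)
    idx = {v: k for k, v in enumerate(ids)}
    dose = haps.sum(2)
    bgmask = arch.background_mask
    vb = dose[:, bgmask] @ arch.background_effects
    tcount = dose[:, arch.target_loci].sum(1)
    wstar = arch.max_background_gebv + 1
    return sum(wstar * tcount[idx[a]] + vb[idx[b]] for a, b, _ in plan.pairs)


class TestSelectBgsIc:
    def test_unique_feasible_backcross(self):
        """A lone positive individual below the recovery goal can only be the
        GEBV-contributing member of an RP pair: the backcross is forced."""
        ctx = make_ctx(4, [1], rc_goal=0.9)
        pop = pop_from_doses([[2, 1, 1, 1]])  # RC = 4/6 < 0.9
        plan = select_bgs_ic(pop, 1, ctx)
        assert plan.pairs == [("RP", "i0", "backcross")]

    def test_self_preferred_when_candidate_meets_goal(self):
        """As printed, the objective credits member i's target alleles with
        W*, so a goal-meeting positive individual selfs rather than
        backcrosses (the RP contributes no target alleles as member i)."""
        ctx = make_ctx(4, [1], rc_goal=0.9)
        pop = pop_from_doses([[2, 1, 2, 2]])  # RC = 1
        plan = select_bgs_ic(pop, 1, ctx)
        assert plan.pairs == [("i0", "i0", "self")]

    def test_matches_enumeration_on_random_instances(self, rng):
        mismatches = 0
        for _ in range(80):
            P = 6
            N = int(rng.integers(3, 8))
            NC = int(rng.integers(1, 4))
            ctx = make_ctx(P, [2], rc_goal=0.5, effects=rng.random(P) + 0.1)
            pop = Population(
                rng.integers(0, 2, (N, P, 2), dtype=np.uint8),
                [f"i{k}" for k in range(N)],
                generation=1,
            )
            plan = select_bgs_ic(pop, NC, ctx)
            best = ilp_brute_force(pop, NC, ctx)
            if len(plan) == NC:
                if best is None or abs(plan_objective(plan, pop, ctx) - best) > 1e-9:
                    mismatches += 1
            elif best is not None:
                mismatches += 1
        assert mismatches == 0

    def test_infeasible_count_relaxes(self):
        ctx = make_ctx(4, [1], rc_goal=0.99)
        pop = pop_from_doses([[2, 1, 2, 2]])
        plan = select_bgs_ic(pop, 3, ctx)  # only one disjoint cross exists
        assert len(plan) == 1

    def test_wstar_choice_does_not_change_optimum(self, rng):
        for _ in range(10):
            P, N, NC = 5, 6, 2
            ctx = make_ctx(P, [1], rc_goal=0.5, effects=rng.random(P) + 0.1)
            pop = Population(
                rng.integers(0, 2, (N, P, 2), dtype=np.uint8),
                [f"i{k}" for k in range(N)],
                generation=1,
            )
            p1 = select_bgs_ic(pop, NC, ctx)
            p2 = select_bgs_ic(pop, NC, ctx, wstar=ctx.arch.max_background_gebv + 1000.0)
            assert plan_objective(p1, pop, ctx) == pytest.approx(plan_objective(p2, pop, ctx))

    def test_every_selected_pair_covers_targets(self, rng):
        ctx = make_ctx(6, [1, 4], rc_goal=0.4)
        pop = Population(
            rng.integers(0, 2, (10, 6, 2), dtype=np.uint8),
            [f"i{k}" for k in range(10)],
            generation=1,
        )
        plan = select_bgs_ic(pop, 3, ctx)
        lookup = {ctx.rp.id: ctx.rp} | {pop.ids[i]: pop.individual(i) for i in range(len(pop))}
        for a, b, _ in plan.pairs:
            dose = lookup[a].dose() + lookup[b].dose()
            assert np.all(dose[ctx.arch.target_loci] >= 1)


class TestSelectPcvIc:
    def test_backcross_chosen_when_one_parent_dominates(self):
        ctx = make_ctx(4, [1], rc_goal=0.5)
        pop = pop_from_doses([[2, 2, 2, 2], [0, 1, 0, 0]])
        plan = select_pcv_ic(pop, 1, ctx)
        a, b, ctype = plan.pairs[0]
        assert "i0" in (a, b)

    def test_complementary_parents_eligible(self):
        """Two parents covering disjoint halves of the targets can pair here
        although neither is positive (impossible in any BC strategy)."""
        ctx = make_ctx(6, [1, 4], rc_goal=0.3)
        pop = pop_from_doses([[2, 2, 2, 0, 0, 0], [0, 0, 0, 2, 2, 2]])
        plan = select_pcv_ic(pop, 1, ctx, top_frac=1.0)
        assert sorted(p for p in plan.pairs[0][:2]) == ["i0", "i1"]

    def test_single_use_of_non_rp_individuals(self, rng):
        ctx = make_ctx(5, [2], rc_goal=0.3)
        rows = rng.integers(0, 3, (8, 5))
        rows[:, 2] = 2
        pop = pop_from_doses(rows)
        plan = select_pcv_ic(pop, 4, ctx, top_frac=1.0)
        non_rp = [m for a, b, _ in plan.pairs for m in (a, b) if m != "RP"]
        # a self uses the same id twice in one pair but in no other pair
        seen_pairs = [tuple(sorted((a, b))) for a, b, _ in plan.pairs]
        assert len(set(seen_pairs)) == len(seen_pairs)
        for m in set(non_rp):
            appearances = sum(1 for a, b, _ in plan.pairs if m in (a, b))
            assert appearances <= 1


class TestCandidatePairFilter:
    def test_f1_with_rp_backcross_ranks_first(self):
        """Cohort of two F1 copies: selfs, intercrosses and backcrosses all
        pass both criteria, and the backcrosses (maximal summed background
        GEBV, thanks to the RP) head the pool."""
        ctx = make_ctx(4, [1], rc_goal=0.5)
        pop = pop_from_doses([[1, 1, 1, 1], [1, 1, 1, 1]])
        pool = candidate_pair_filter(pop, ctx, fraction=1.0)
        named = [tuple(sorted((pool.ids[i], pool.ids[j]))) for i, j in pool.pairs]
        assert len(pool) == 2
        assert all("RP" in pair for pair in named)

    def test_truncation_to_single_best_pair(self):
        ctx = make_ctx(4, [1], rc_goal=0.5)
        pop = pop_from_doses([[1, 1, 1, 1], [1, 2, 2, 2], [2, 1, 0, 2]])
        pool = candidate_pair_filter(pop, ctx, fraction=1e-6)
        assert len(pool) == 1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_filter_postconditions(self, seed):
        """Every surviving pair covers the targets and exceeds the goal in
        joint background potential (or comes from the coverage fallback)."""
        rng = np.random.default_rng(seed)
        ctx = make_ctx(6, [2], rc_goal=0.6)
        pop = Population(
            rng.integers(0, 2, (7, 6, 2), dtype=np.uint8),
            [f"i{k}" for k in range(7)],
            generation=1,
        )
        pool = candidate_pair_filter(pop, ctx, fraction=0.5)
        from tisim.genetics_core import genetic_potential

        all_inds = [pop.individual(i) for i in range(len(pop))] + [ctx.rp]
        bl = np.flatnonzero(ctx.arch.background_mask)
        strict = []
        for i, j in pool.pairs:
            a, b = all_inds[i], all_inds[j]
            assert genetic_potential(a, b, ctx.arch.target_loci) == 1.0
            strict.append(genetic_potential(a, b, bl) > ctx.arch.rc_goal)
        # either every pair satisfies the strict criterion or the filter fell
        # back to coverage-only pairs as a whole
        assert all(strict) or not any(strict) or len(pool) == 0


class TestLasIcEvaluate:
    def test_fixed_seed_reproducible(self):
        ctx = make_ctx(5, [2], seed=21, reps=3, K=25)
        a = pop_from_doses([[1, 1, 2, 1, 1]]).individual(0)
        v1 = las_ic_evaluate(a, a, ctx.las, ctx, t=2, pop_size=25)
        ctx2 = make_ctx(5, [2], seed=21, reps=3, K=25)
        v2 = las_ic_evaluate(a, a, ctx2.las, ctx2, t=2, pop_size=25)
        assert v1 == v2

    def test_impossible_goal_scores_zero(self):
        """With a perfect-recovery goal and a fixed unfavorable background
        allele, no descendant can ever succeed."""
        ctx = make_ctx(5, [2], rc_goal=1.0, seed=2, reps=4, K=25)
        a = pop_from_doses([[0, 2, 2, 2, 2]]).individual(0)  # locus 0 fixed bad
        assert las_ic_evaluate(a, a, ctx.las, ctx, t=3, pop_size=25) == 0.0

    def test_deterministically_successful_pair(self):
        """Both parents fixed at the targets with RP-like background: every
        selfed progeny is successful, so V approaches the maximal VB."""
        ctx = make_ctx(5, [2], rc_goal=0.9, seed=4, reps=30, K=40)
        a = pop_from_doses([[2, 2, 2, 2, 2]]).individual(0)
        v = las_ic_evaluate(a, a, ctx.las, ctx, t=3, pop_size=40)
        assert v == pytest.approx(ctx.arch.max_background_gebv, rel=0.02)


class TestSelectLasIc:
    def test_plan_equals_pool_when_sizes_match(self):
        ctx = make_ctx(5, [2], rc_goal=0.4, seed=6, reps=2, K=20)
        pop = pop_from_doses([[1, 1, 2, 1, 1], [2, 2, 1, 0, 1]], generation=2)
        pool = candidate_pair_filter(pop, ctx, ctx.las.outer_frac, cap=ctx.las.outer_cap)
        plan = select_las_ic(pop, len(pool), ctx)
        assert len(plan) == len(pool)

    def test_matched_seed_determinism(self):
        plans = []
        for _ in range(2):
            ctx = make_ctx(6, [3], rc_goal=0.4, seed=13, reps=2, K=20)
            pop = pop_from_doses(
                [[1, 2, 1, 1, 0, 2], [2, 1, 0, 2, 2, 1], [1, 1, 2, 1, 1, 1]], generation=2
            )
            plans.append(select_las_ic(pop, 2, ctx).pairs)
        assert plans[0] == plans[1]

    def test_larger_pool_never_lowers_best_score(self):
        """Enlarging the candidate pool at a matched seed only appends pairs
        (pools are GEBV-sorted prefixes), so the best look-ahead score among
        selected pairs cannot decrease."""
        from tisim.strategy_ic import las_ic_evaluate

        def best_score(cap):
            ctx = make_ctx(6, [3], rc_goal=0.4, seed=17, reps=3, K=20)
            pop = pop_from_doses(
                [[1, 2, 1, 1, 0, 2], [2, 1, 0, 2, 2, 1], [1, 1, 2, 1, 1, 1],
                 [2, 2, 1, 2, 1, 0]], generation=2
            )
            pool = candidate_pair_filter(pop, ctx, fraction=1.0, cap=cap)
            scores = []
            for i, j in pool.pairs:
                a = Individual(pool.ids[i], pool.haps[i])
                b = Individual(pool.ids[j], pool.haps[j])
                scores.append(las_ic_evaluate(a, b, ctx.las, ctx, t=2, pop_size=len(pop)))
            return max(scores)

        assert best_score(6) >= best_score(2)

    def test_selected_pairs_cover_targets(self):
        ctx = make_ctx(6, [1, 4], rc_goal=0.3, seed=8, reps=2, K=20)
        pop = pop_from_doses(
            [[2, 2, 2, 0, 0, 0], [0, 0, 0, 2, 2, 2], [1, 1, 1, 1, 1, 1]], generation=2
        )
        plan = select_las_ic(pop, 2, ctx)
        lookup = {ctx.rp.id: ctx.rp} | {pop.ids[i]: pop.individual(i) for i in range(len(pop))}
        for a, b, _ in plan.pairs:
            dose = lookup[a].dose() + lookup[b].dose()
            assert np.all(dose[ctx.arch.target_loci] >= 1)
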