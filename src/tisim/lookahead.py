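"""Vectorized look-ahead Monte Carlo machinery shared by the LAS strategies.

A look-ahead simulation projects a proposed cross forward to a target
generation ``T``: intermediate generations are simulated with K progeny per
cross, the population at ``T - 1`` is selfed, and the selfed cohort is scored
by the expected-performance statistic

    V = (1/Npos) * sum_i VB_i * n_i / K

where the sum runs over the (up to) ``Npos`` best positive individuals of
the ``T - 1`` population, ``VB_i`` is the maximum background GEBV among the
K selfed progeny of individual i and ``n_i`` the number of successful ones.

All repetitions of a simulation are advanced simultaneously; cohorts are
kept as two ``(reps, K, P)`` uint8 haplotype planes so every meiosis is one
batched sampler call.  One call evaluates one candidate (individual or pair).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .genetics_core import TraitArchitecture
from .meiosis import GameteModel, _sample_sources, sample_gametes, sample_gametes_planes

__all__ = ["selfed_performance_scores", "lookahead_bc_score", "lookahead_ic_score"]


@njit(cache=True)
def _stats_kernel(g1, g2, tl_idx, bg_idx, wbg, thr_sum, require_fixed, flag, vb):
    """Per-row classification and background GEBV in one pass.

    ``flag`` is 1 when the row is positive (or, with ``require_fixed``,
    homozygous favorable at every target locus) and its background allele
    sum reaches ``thr_sum`` (the recovery-rate goal in allele-count units).
    """
    B = g1.shape[0]
    for i in range(B):
        ok = True
        for t in tl_idx:
            d = g1[i, t] + g2[i, t]
            if require_fixed:
                if d != 2:
                    ok = False
                    break
            elif d == 0:
                ok = False
                break
        s = 0
        v = 0.0
        for a in range(bg_idx.size):
            p = bg_idx[a]
            d = g1[i, p] + g2[i, p]
            s += d
            v += d * wbg[a]
        vb[i] = v
        flag[i] = 1 if (ok and s >= thr_sum) else 0


@njit(cache=True)
def _self_eval_kernel(
    cw0, cw1, cc0, cc1, a0, a1, marker_x, seg_bounds, tl_idx,
    offs1, pos1, st1, offs2, pos2, st2, K, thr, succ, vb,
):
    """Self parents and score each progeny without materializing gametes.

    A selfed progeny is two independent meioses of the same parent; each
    gamete is a sequence of parental-haplotype chunks delimited by its
    crossover events, so the progeny's background GEBV and allele sum are
    sums of precomputed per-haplotype prefix-sum differences (``cw*`` for
    effect-weighted, ``cc*`` for counts), and only the few target loci are
    looked up individually.
    """
    nG = succ.size
    nseg = seg_bounds.size - 1
    nTL = tl_idx.size
    tld = np.zeros(nTL, dtype=np.int64)
    for gi in range(nG):
        par = gi // K
        for t in range(nTL):
            tld[t] = 0
        v = 0.0
        c = 0
        for which in range(2):
            if which == 0:
                ev = np.sort(pos1[offs1[gi] : offs1[gi + 1]])
                starts = st1
            else:
                ev = np.sort(pos2[offs2[gi] : offs2[gi + 1]])
                starts = st2
            m = ev.size
            kk = 0
            tp = 0
            for s in range(nseg):
                a = seg_bounds[s]
                b = seg_bounds[s + 1]
                src = starts[gi, s]
                p = a
                while p < b:
                    if kk < m and ev[kk] <= marker_x[b - 1]:
                        q = p
                        while marker_x[q] < ev[kk]:
                            q += 1
                        # chunk [p, q) with the current source
                        if src == 0:
                            v += cw0[par, q] - cw0[par, p]
                            c += cc0[par, q] - cc0[par, p]
                        else:
                            v += cw1[par, q] - cw1[par, p]
                            c += cc1[par, q] - cc1[par, p]
                        while tp < nTL and tl_idx[tp] < q:
                            tld[tp] += a0[par, tp] if src == 0 else a1[par, tp]
                            tp += 1
                        while kk < m and ev[kk] <= marker_x[q]:
                            src ^= np.uint8(1)
                            kk += 1
                        # marker q with the post-crossover source
                        if src == 0:
                            v += cw0[par, q + 1] - cw0[par, q]
                            c += cc0[par, q + 1] - cc0[par, q]
                        else:
                            v += cw1[par, q + 1] - cw1[par, q]
                            c += cc1[par, q + 1] - cc1[par, q]
                        if tp < nTL and tl_idx[tp] == q:
                            tld[tp] += a0[par, tp] if src == 0 else a1[par, tp]
                            tp += 1
                        p = q + 1
                    else:
                        if src == 0:
                            v += cw0[par, b] - cw0[par, p]
                            c += cc0[par, b] - cc0[par, p]
                        else:
                            v += cw1[par, b] - cw1[par, p]
                            c += cc1[par, b] - cc1[par, p]
                        while tp < nTL and tl_idx[tp] < b:
                            tld[tp] += a0[par, tp] if src == 0 else a1[par, tp]
                            tp += 1
                        p = b
        vb[gi] = v
        ok = c >= thr
        if ok:
            for t in range(nTL):
                if tld[t] != 2:
                    ok = False
                    break
        succ[gi] = 1 if ok else 0


def _self_and_score(
    ph1: np.ndarray,
    ph2: np.ndarray,
    arch: TraitArchitecture,
    model: GameteModel,
    K: int,
    rng: np.random.Generator,
):
    """(success flag, background GEBV) for K selfed progeny of each parent row."""
    n_par, P = ph1.shape
    bg = arch.background_mask
    wmask = arch.effects * bg
    zero = np.zeros((n_par, 1))
    cw0 = np.concatenate([zero, np.cumsum(ph1 * wmask, axis=1)], axis=1)
    cw1 = np.concatenate([zero, np.cumsum(ph2 * wmask, axis=1)], axis=1)
    izero = np.zeros((n_par, 1), dtype=np.int64)
    cc0 = np.concatenate([izero, np.cumsum(ph1 * bg, axis=1, dtype=np.int64)], axis=1)
    cc1 = np.concatenate([izero, np.cumsum(ph2 * bg, axis=1, dtype=np.int64)], axis=1)
    tl = arch.target_loci.astype(np.int64)
    a0 = np.ascontiguousarray(ph1[:, tl])
    a1 = np.ascontiguousarray(ph2[:, tl])
    nG = n_par * K
    offs1, pos1, st1 = _sample_sources(model, nG, rng)
    offs2, pos2, st2 = _sample_sources(model, nG, rng)
    thr = math.ceil(arch.rc_goal * 2 * int(bg.sum()) - 1e-9)
    succ = np.empty(nG, dtype=np.uint8)
    vb = np.empty(nG, dtype=np.float64)
    _self_eval_kernel(
        cw0, cw1, cc0, cc1, a0, a1, model.marker_x, model.seg_bounds, tl,
        offs1, pos1, st1, offs2, pos2, st2, K, thr, succ, vb,
    )
    return succ.astype(bool), vb


def _row_stats(g1, g2, arch: TraitArchitecture, require_fixed: bool, apply_rc: bool):
    """flag/VB arrays for flattened ``(B, P)`` gamete planes."""
    B = g1.shape[0]
    flag = np.empty(B, dtype=np.uint8)
    vb = np.empty(B, dtype=np.float64)
    nbg = int(arch.background_mask.sum())
    thr = math.ceil(arch.rc_goal * 2 * nbg - 1e-9) if apply_rc else 0
    _stats_kernel(
        np.ascontiguousarray(g1),
        np.ascontiguousarray(g2),
        arch.target_loci.astype(np.int64),
        np.flatnonzero(arch.background_mask).astype(np.int64),
        arch.background_effects,
        thr,
        require_fixed,
        flag,
        vb,
    )
    return flag.astype(bool), vb


def selfed_performance_scores(
    cohort_h1: np.ndarray,
    cohort_h2: np.ndarray,
    arch: TraitArchitecture,
    model: GameteModel,
    K: int,
    npos: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Score per repetition of the terminal selfing step.

    ``cohort_h1``/``cohort_h2`` are ``(R, n, P)`` haplotype planes of the
    generation-``T-1`` cohorts (one cohort of size ``n`` per repetition).
    The top-``npos`` positive individuals of each cohort (by background
    GEBV) are selfed for ``K`` progeny each.
    """
    R, n, P = cohort_h1.shape
    npos = min(npos, n)
    pos, vb = _row_stats(
        cohort_h1.reshape(R * n, P), cohort_h2.reshape(R * n, P), arch,
        require_fixed=False, apply_rc=False,
    )
    pos = pos.reshape(R, n)
    vb = vb.reshape(R, n)
    rank_key = np.where(pos, vb, -1.0)
    top = np.argpartition(-rank_key, npos - 1, axis=1)[:, :npos]
    rows = np.arange(R)[:, None]
    valid = pos[rows, top]  # (R, npos)
    if not valid.any():
        return np.zeros(R)
    # self each selected parent for K progeny (two independent gametes each)
    ph1 = cohort_h1[rows, top].reshape(R * npos, P)
    ph2 = cohort_h2[rows, top].reshape(R * npos, P)
    succ, svb = _self_and_score(ph1, ph2, arch, model, K, rng)
    n_i = succ.reshape(R, npos, K).sum(axis=2)
    vb_i = svb.reshape(R, npos, K).max(axis=2)
    contrib = np.where(valid, vb_i * (n_i / K), 0.0)
    return contrib.sum(axis=1) / npos


def lookahead_bc_score(
    ind_haps: np.ndarray,
    rp_haps: np.ndarray,
    arch: TraitArchitecture,
    model: GameteModel,
    reps: int,
    K: int,
    npos: int,
    n_crosses: int,
    rng: np.random.Generator,
) -> float:
    """Expected selfed-cohort performance of repeatedly backcrossing one candidate.

    Simulates ``n_crosses`` successive backcrosses to the recurrent parent
    (a random positive progeny carries each intermediate generation), selfs
    the final cohort's positives, and averages the score over ``reps``
    repetitions advanced in parallel.
    """
    P = ind_haps.shape[0]
    R = reps
    tl = arch.target_loci
    h1 = np.repeat(np.asarray(ind_haps[:, 0], dtype=np.uint8)[None], R, axis=0)
    h2 = np.repeat(np.asarray(ind_haps[:, 1], dtype=np.uint8)[None], R, axis=0)
    for step in range(n_crosses):
        g1 = sample_gametes_planes(np.repeat(h1, K, axis=0), np.repeat(h2, K, axis=0), model, rng)
        g2 = sample_gametes(rp_haps, model, R * K, rng)
        if step == n_crosses - 1:
            return float(
                selfed_performance_scores(
                    g1.reshape(R, K, P), g2.reshape(R, K, P), arch, model, K, npos, rng
                ).mean()
            )
        dose_tl = g1[:, tl] + g2[:, tl]
        pos = (dose_tl >= 1).all(axis=1).reshape(R, K)
        # random positive progeny per repetition; fall back to any progeny
        order = np.argsort(~pos, axis=1, kind="stable")
        counts = pos.sum(axis=1)
        pick = (rng.random(R) * np.where(counts > 0, counts, K)).astype(np.int64)
        sel = order[np.arange(R), pick] + np.arange(R) * K
        h1, h2 = g1[sel], g2[sel]
    raise AssertionError("n_crosses must be >= 1")


def _inner_pair_choice(
    h1: np.ndarray,
    h2: np.ndarray,
    rp_haps: np.ndarray,
    arch: TraitArchitecture,
    pool_size: int,
    rng: np.random.Generator,
):
    """Pick one candidate pair per repetition from each simulated cohort.

    Applies the candidate-pair filter (full target-locus coverage, joint
    background potential above the goal, rank by summed background GEBV),
    truncates to ``pool_size`` and samples one surviving pair uniformly.
    Returns per-repetition parent indices into the cohort-plus-RP block and
    an alive mask.
    """
    R, n, P = h1.shape
    tl, bg = arch.target_loci, arch.background_mask
    wbg = arch.background_effects.astype(np.float32)
    m = n + 1  # cohort plus the recurrent parent
    H1 = np.concatenate([h1, np.broadcast_to(rp_haps[:, 0], (R, 1, P))], axis=1)
    H2 = np.concatenate([h2, np.broadcast_to(rp_haps[:, 1], (R, 1, P))], axis=1)
    dose = H1 + H2
    # bitmask of uncovered target loci per individual
    code = np.zeros((R, m), dtype=np.int64)
    for k, t in enumerate(tl):
        code |= (dose[:, :, t] == 0).astype(np.int64) << k
    cov = (code[:, :, None] & code[:, None, :]) == 0  # joint TL coverage
    zbg = (dose[:, :, bg] == 0).astype(np.float32)
    both0 = zbg @ zbg.transpose(0, 2, 1)
    gp_bl = 1.0 - both0 / np.float32(bg.sum())
    vb = ((dose[:, :, bg]).astype(np.float32) @ wbg).astype(np.float64)
    vbsum = vb[:, :, None] + vb[:, None, :]
    triu = np.triu(np.ones((m, m), dtype=bool))
    elig1 = cov & triu
    elig2 = elig1 & (gp_bl > arch.rc_goal)
    idx_a = np.zeros(R, dtype=np.int64)
    idx_b = np.zeros(R, dtype=np.int64)
    alive = np.zeros(R, dtype=bool)
    flat2 = np.where(elig2, vbsum, -np.inf).reshape(R, -1)
    flat1 = np.where(elig1, vbsum, -np.inf).reshape(R, -1)
    for r in range(R):
        score = flat2[r]
        k = int(np.isfinite(score).sum())
        if k == 0:  # fallback: coverage-only pairs
            score = flat1[r]
            k = int(np.isfinite(score).sum())
            if k == 0:
                continue
        take = min(pool_size, k)
        pool = np.argpartition(-score, take - 1)[:take]
        choice = pool[rng.integers(take)]
        idx_a[r], idx_b[r] = divmod(int(choice), m)
        alive[r] = True
    return H1, H2, idx_a, idx_b, alive


def lookahead_ic_score(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    rp_haps: np.ndarray,
    arch: TraitArchitecture,
    model: GameteModel,
    reps: int,
    K: int,
    npos: int,
    n_inner: int,
    inner_pool_size: int,
    rng: np.random.Generator,
) -> float:
    """Expected selfed-cohort performance of one candidate pair in the IC pipeline.

    The pair is crossed, then ``n_inner`` further generations are simulated
    by re-applying the candidate-pair filter to each repetition's cohort and
    crossing one uniformly chosen surviving pair; the final cohort is selfed
    and scored.  Repetitions whose filter yields no pair score 0.
    """
    P = hap_a.shape[0]
    R = reps
    g1 = sample_gametes(hap_a, model, R * K, rng).reshape(R, K, P)
    g2 = sample_gametes(hap_b, model, R * K, rng).reshape(R, K, P)
    alive = np.ones(R, dtype=bool)
    for _ in range(n_inner):
        H1, H2, ia, ib, ok = _inner_pair_choice(g1, g2, rp_haps, arch, inner_pool_size, rng)
        alive &= ok
        rows = np.arange(R)
        pa1 = np.repeat(H1[rows, ia], K, axis=0)
        pa2 = np.repeat(H2[rows, ia], K, axis=0)
        pb1 = np.repeat(H1[rows, ib], K, axis=0)
        pb2 = np.repeat(H2[rows, ib], K, axis=0)
        g1 = sample_gametes_planes(pa1, pa2, model, rng).reshape(R, K, P)
        g2 = sample_gametes_planes(pb1, pb2, model, rng).reshape(R, K, P)
    scores = selfed_performance_scores(g1, g2, arch, model, K, npos, rng)
    scores[~alive] = 0.0
    return float(scores.mean())
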