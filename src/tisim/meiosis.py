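"""Gamete sampling and cross simulation under a no-interference model.

Meiosis is modelled as a two-state Markov chain over ordered loci: the
gamete starts on either parental haplotype with probability 1/2 and switches
source between loci ``p`` and ``p+1`` with probability ``rf[p]``.  Intervals
with ``rf = 0.5`` (chromosome boundaries) re-randomize the source, giving
free assortment across chromosomes.

Two samplers are provided:

* :func:`sample_gametes` — the default.  It draws crossover *events* from a
  Poisson process on the map transformed through the inverse Haldane map
  (interval ``p`` has effective length ``-ln(1 - 2 rf[p]) / 2`` Morgans) and
  takes the per-interval event parity as the switch indicator.  Under the
  no-interference model this is distributionally identical to the
  interval-by-interval Bernoulli chain but needs roughly an order of
  magnitude fewer random draws.
* :func:`sample_gametes_naive` — the literal Bernoulli chain, kept as an
  in-repo cross-check.

:func:`enumerate_gamete_distribution` enumerates the exact gamete
distribution for small marker counts and is the oracle both samplers are
validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .genetics_core import Individual, Population

__all__ = [
    "GameteModel",
    "sample_gametes",
    "sample_gametes_naive",
    "sample_gamete",
    "make_cross",
    "cross_progeny_haps",
    "enumerate_gamete_distribution",
    "ENUMERATION_CAP",
]

#: Largest marker count accepted by the exhaustive gamete enumeration.
ENUMERATION_CAP = 12

_BOUNDARY = 0.5  # rf exactly 0.5 marks free assortment


@dataclass
class GameteModel:
    """Recombination-frequency vector with precomputed sampling tables."""

    rf: np.ndarray
    seg_starts: np.ndarray = field(init=False, repr=False)
    seg_bounds: np.ndarray = field(init=False, repr=False)
    marker_x: np.ndarray = field(init=False, repr=False)
    total_len: float = field(init=False, repr=False)

    def __post_init__(self):
        self.rf = np.asarray(self.rf, dtype=float)
        if np.any((self.rf <= 0) | (self.rf > 0.5)):
            raise ValueError("rf entries must lie in (0, 0.5]")
        P = len(self.rf) + 1
        boundary = self.rf >= _BOUNDARY
        # markers that start a new linkage segment (free assortment before them)
        self.seg_starts = np.concatenate(([0], np.flatnonzero(boundary) + 1))
        # cumulative effective Morgan coordinate of each marker, skipping
        # boundary intervals (inverse Haldane map of each finite interval)
        u = np.where(boundary, 0.0, -0.5 * np.log1p(-2.0 * np.minimum(self.rf, 0.5 - 1e-12)))
        self.marker_x = np.concatenate(([0.0], np.cumsum(u)))
        self.total_len = float(self.marker_x[-1])
        self.n_markers = P
        self.seg_bounds = np.concatenate((self.seg_starts, [P])).astype(np.int64)


@njit(cache=True)
def _gamete_kernel(h0, h1, multi, marker_x, seg_bounds, offsets, pos, starts, out):
    """Fill ``out[g, :]`` with the alleles the g-th gamete copies.

    ``pos`` holds the crossover-event coordinates of all gametes
    (``offsets`` delimits each gamete's slice), ``starts`` the uniform
    source bit drawn at every segment start.  Markers between consecutive
    crossovers are copied from the current source haplotype in bulk.
    """
    n, P = out.shape
    nseg = seg_bounds.size - 1
    for g in range(n):
        ev = np.sort(pos[offsets[g] : offsets[g + 1]])
        m = ev.size
        k = 0
        row0 = h0[g] if multi else h0[0]
        row1 = h1[g] if multi else h1[0]
        for s in range(nseg):
            a = seg_bounds[s]
            b = seg_bounds[s + 1]
            src = starts[g, s]
            p = a
            while p < b:
                row = row0 if src == 0 else row1
                if k < m and ev[k] <= marker_x[b - 1]:
                    q = p
                    while marker_x[q] < ev[k]:
                        q += 1
                    out[g, p:q] = row[p:q]
                    while k < m and ev[k] <= marker_x[q]:
                        src ^= np.uint8(1)
                        k += 1
                    row = row0 if src == 0 else row1
                    out[g, q] = row[q]
                    p = q + 1
                else:
                    out[g, p:b] = row[p:b]
                    p = b


def _sample_sources(model: GameteModel, n: int, rng: np.random.Generator):
    counts = rng.poisson(model.total_len, size=n) if model.total_len > 0 else np.zeros(n, np.int64)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    pos = rng.random(int(offsets[-1])) * model.total_len
    starts = rng.integers(0, 2, size=(n, len(model.seg_starts)), dtype=np.uint8)
    return offsets, pos, starts


def sample_gametes(haps: np.ndarray, model: GameteModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent gametes from one parent.

    ``haps`` is the parent's ``(P, 2)`` haplotype matrix; returns ``(n, P)``.
    """
    haps = np.asarray(haps, dtype=np.uint8)
    if haps.shape != (model.n_markers, 2):
        raise ValueError("haps must be (P, 2) and match the model's marker count")
    if np.array_equal(haps[:, 0], haps[:, 1]):
        return np.broadcast_to(haps[:, 0], (n, model.n_markers)).copy()
    offsets, pos, starts = _sample_sources(model, n, rng)
    out = np.empty((n, model.n_markers), dtype=np.uint8)
    _gamete_kernel(
        np.ascontiguousarray(haps[:, 0])[None],
        np.ascontiguousarray(haps[:, 1])[None],
        False,
        model.marker_x,
        model.seg_bounds,
        offsets,
        pos,
        starts,
        out,
    )
    return out


def sample_gametes_planes(
    h0: np.ndarray, h1: np.ndarray, model: GameteModel, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per row, parents given as two ``(B, P)`` haplotype planes."""
    B = h0.shape[0]
    offsets, pos, starts = _sample_sources(model, B, rng)
    out = np.empty((B, model.n_markers), dtype=np.uint8)
    _gamete_kernel(
        np.ascontiguousarray(h0),
        np.ascontiguousarray(h1),
        True,
        model.marker_x,
        model.seg_bounds,
        offsets,
        pos,
        starts,
        out,
    )
    return out


def sample_gametes_multi(haps: np.ndarray, model: GameteModel, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of a ``(B, P, 2)`` stack of parent haplotypes."""
    haps = np.asarray(haps, dtype=np.uint8)
    return sample_gametes_planes(haps[:, :, 0], haps[:, :, 1], model, rng)


def sample_gametes_naive(haps: np.ndarray, model: GameteModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Literal Bernoulli-per-interval Markov-chain sampler (cross-check)."""
    haps = np.asarray(haps, dtype=np.uint8)
    P = model.n_markers
    parity = np.zeros((n, P), dtype=np.uint8)
    parity[:, 1:] = rng.random((n, P - 1)) < model.rf
    parity[:, 0] = rng.integers(0, 2, size=n, dtype=np.uint8)
    src = np.bitwise_xor.accumulate(parity, axis=1)
    return np.where(src == 0, haps[:, 0], haps[:, 1])


def sample_gamete(ind: Individual, model: GameteModel, rng: np.random.Generator) -> np.ndarray:
    """A single gamete (length-P 0/1 vector) from ``ind``."""
    return sample_gametes(ind.haplotypes, model, 1, rng)[0]


def cross_progeny_haps(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    K: int,
    model: GameteModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """``(K, P, 2)`` progeny haplotypes of one cross (maternal gamete first)."""
    g1 = sample_gametes(hap_a, model, K, rng)
    g2 = sample_gametes(hap_b, model, K, rng)
    return np.stack([g1, g2], axis=2)


def make_cross(
    p1: Individual,
    p2: Individual,
    K: int,
    model: GameteModel,
    rng: np.random.Generator,
    generation: int = 0,
    rp_id: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> Population:
    """Cross two parents and return ``K`` progeny as a Population.

    Cross type is inferred from identities: same parent -> ``self``, one
    parent equal to ``rp_id`` -> ``backcross``, else ``intercross``.
    Reciprocal crosses are identical by construction.
    """
    if K <= 0:
        raise ValueError("progeny count K must be >= 1")
    if p1.id == p2.id:
        ctype = "self"
    elif rp_id is not None and rp_id in (p1.id, p2.id):
        ctype = "backcross"
    else:
        ctype = "intercross"
    haps = cross_progeny_haps(p1.haplotypes, p2.haplotypes, K, model, rng)
    prefix = id_prefix or f"{p1.id}x{p2.id}"
    ids = [f"{prefix}_{k}" for k in range(K)]
    return Population(
        haps,
        ids,
        generation=generation,
        parent_a=[p1.id] * K,
        parent_b=[p2.id] * K,
        cross_type=[ctype] * K,
    )


def enumerate_gamete_distribution(ind: Individual, rf: np.ndarray):
    """Exact gamete distribution of one parent for small ``P``.

    Collapses the ``2^P`` source-haplotype Markov paths over equal gametes;
    returns a list of ``(gamete tuple, probability)`` sorted by gamete, with
    probabilities summing to 1.  Refuses ``P`` above :data:`ENUMERATION_CAP`.
    """
    rf = np.asarray(rf, dtype=float)
    h = np.asarray(ind.haplotypes, dtype=np.uint8)
    P = h.shape[0]
    if P > ENUMERATION_CAP:
        raise ValueError(
            f"P={P} exceeds the enumeration cap ({ENUMERATION_CAP}); "
            "use the Monte Carlo sampler instead"
        )
    if len(rf) != P - 1:
        raise ValueError("rf must have length P - 1")
    # prefix gamete -> [P(source=hap0), P(source=hap1)] at the current locus
    states: dict = {}
    for src in (0, 1):
        key = (int(h[0, src]),)
        states.setdefault(key, np.zeros(2))[src] += 0.5
    for p in range(1, P):
        r = rf[p - 1]
        nxt: dict = {}
        for prefix, pr in states.items():
            stay0 = pr[0] * (1 - r) + pr[1] * r
            stay1 = pr[0] * r + pr[1] * (1 - r)
            for src, mass in ((0, stay0), (1, stay1)):
                if mass == 0.0:
                    continue
                key = prefix + (int(h[p, src]),)
                vec = nxt.setdefault(key, np.zeros(2))
                vec[src] += mass
        states = nxt
    out = [(g, float(v.sum())) for g, v in states.items()]
    out.sort(key=lambda t: t[0])
    return out
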