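"""Core domain types and scalar genetics quantities for trait introgression.

The simulator works on phased, biallelic marker data coded so that ``1``
always means the *favorable* allele.  An individual is a ``P x 2`` binary
haplotype matrix (diploids only); the trait architecture singles out a small
set of target loci to be introgressed from a donor, every other locus being
"background" whose favorable alleles come from the recurrent parent.

Quantities defined here:

* background recovery rate ``RC`` — fraction of favorable alleles over the
  background loci;
* genetic potential ``GP`` — fraction of a locus set at which two candidate
  parents jointly carry at least one favorable allele;
* background GEBV ``VB`` — effect-weighted favorable-allele count over the
  background loci;
* positive / successful individual classification;
* Haldane map-distance <-> recombination-fraction conversion and the
  per-interval recombination-frequency vector ``RF``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RF_FLOOR",
    "GeneticMap",
    "TraitArchitecture",
    "Pedigree",
    "Individual",
    "Population",
    "haldane_rf",
    "inverse_haldane",
    "build_rf_vector",
    "background_recovery_rate",
    "genetic_potential",
    "background_gebv",
    "is_positive",
    "is_successful",
]

#: Lower clip applied to recombination fractions so RF stays in (0, 0.5]
#: even for colocated markers.
RF_FLOOR = 1e-6


def haldane_rf(d_cM):
    """Convert map distance (cM) to recombination fraction via Haldane.

    ``r = 0.5 * (1 - exp(-2 d))`` with ``d`` in Morgans; assumes no
    crossover interference.  Accepts scalars or arrays; distances must be
    nonnegative.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def inverse_haldane(r):
    """Map distance in cM corresponding to recombination fraction ``r`` < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return d if d.ndim else float(d)


def build_rf_vector(chromosome, position_cM, floor: float = RF_FLOOR) -> np.ndarray:
    """Recombination-frequency vector for an ordered genetic map.

    Adjacent markers on the same chromosome get the Haldane fraction of
    their cM gap, clipped into ``[floor, 0.5]``; markers on different
    chromosomes assort freely (``rf = 0.5``).
    """
    chrom = np.asarray(chromosome)
    pos = np.asarray(position_cM, dtype=float)
    if chrom.shape != pos.shape or chrom.ndim != 1:
        raise ValueError("chromosome and position arrays must be 1-D and equal length")
    if len(pos) < 2:
        return np.empty(0, dtype=float)
    order_ok = np.all(
        (chrom[1:] > chrom[:-1]) | ((chrom[1:] == chrom[:-1]) & (pos[1:] >= pos[:-1]))
    )
    if not order_ok:
        raise ValueError("map must be sorted by (chromosome, position_cM); sort it first")
    same = chrom[1:] == chrom[:-1]
    rf = np.full(len(pos) - 1, 0.5)
    rf[same] = np.clip(haldane_rf(pos[1:][same] - pos[:-1][same]), floor, 0.5)
    return rf


@dataclass
class GeneticMap:
    """Ordered marker map with the derived recombination-frequency vector."""

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    rf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids)
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        if not (len(self.marker_ids) == len(self.chromosome) == len(self.position_cM)):
            raise ValueError("map columns must have equal length")
        self._dedupe_positions()
        if self.rf is None:
            self.rf = build_rf_vector(self.chromosome, self.position_cM)
        self.rf = np.asarray(self.rf, dtype=float)
        if len(self.rf) != max(len(self.marker_ids) - 1, 0):
            raise ValueError("rf must have length P - 1")
        if np.any((self.rf <= 0) | (self.rf > 0.5)):
            raise ValueError("rf entries must lie in (0, 0.5]")

    def _dedupe_positions(self):
        # Stable jitter keeps strict ordering for colocated markers.
        pos = self.position_cM.copy()
        dup = False
        for c in np.unique(self.chromosome):
            idx = np.flatnonzero(self.chromosome == c)
            p = pos[idx]
            for k in range(1, len(p)):
                if p[k] <= p[k - 1]:
                    if p[k] == p[k - 1]:
                        dup = True
                    p[k] = p[k - 1] + 1e-9
            pos[idx] = p
        if dup:
            warnings.warn("duplicate map positions jittered by 1e-9 cM", stacklevel=3)
            self.position_cM = pos

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneticMap":
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        t = table.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
        if not t["marker"].equals(table["marker"].reset_index(drop=True)):
            raise ValueError("map table is not sorted by (chrom, pos_cM); sort it first")
        return cls(
            marker_ids=t["marker"].to_numpy(),
            chromosome=t["chrom"].to_numpy(),
            position_cM=t["pos_cM"].to_numpy(),
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chromosome, "pos_cM": self.position_cM}
        )


@dataclass
class TraitArchitecture:
    """Target-locus set, allele-effect vector and the recovery-rate goal.

    ``target_loci`` are 0-based marker indices; ``effects`` (``W``) is a
    nonnegative length-``P`` vector of allele substitution effects;
    ``rc_goal`` is the background recovery rate a successful individual
    must reach (the boundary counts: ``RC >= rc_goal``).
    """

    target_loci: np.ndarray
    effects: np.ndarray
    rc_goal: float

    def __post_init__(self):
        self.target_loci = np.unique(np.asarray(self.target_loci, dtype=int))
        self.effects = np.asarray(self.effects, dtype=float)
        if self.target_loci.size < 1:
            raise ValueError("at least one target locus required")
        if np.any(self.effects < 0):
            raise ValueError("allele effects must be nonnegative")
        P = len(self.effects)
        if np.any((self.target_loci < 0) | (self.target_loci >= P)):
            raise ValueError("target locus index out of range")
        if self.target_loci.size >= P:
            raise ValueError("need at least one background locus")
        if not (0 < self.rc_goal <= 1):
            raise ValueError("rc_goal must lie in (0, 1]")
        mask = np.ones(P, dtype=bool)
        mask[self.target_loci] = False
        self._background_mask = mask

    @property
    def n_markers(self) -> int:
        return len(self.effects)

    @property
    def n_targets(self) -> int:
        return len(self.target_loci)

    @property
    def background_mask(self) -> np.ndarray:
        return self._background_mask

    @property
    def background_effects(self) -> np.ndarray:
        return self.effects[self._background_mask]

    @property
    def max_background_gebv(self) -> float:
        """2 * sum of background effects — VB of the canonical recurrent parent."""
        return 2.0 * float(self.background_effects.sum())


@dataclass
class Pedigree:
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    cross_type: Optional[str] = None  # backcross | intercross | self
    generation: Optional[int] = None


@dataclass
class Individual:
    """One diploid plant: a ``P x 2`` binary haplotype matrix, 1 = favorable."""

    id: str
    haplotypes: np.ndarray
    pedigree: Optional[Pedigree] = None

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must be a P x 2 matrix (diploid)")
        if np.any(self.haplotypes > 1):
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[0]

    def dose(self) -> np.ndarray:
        """Favorable-allele count per locus (0, 1 or 2)."""
        return self.haplotypes.sum(axis=1)

    def is_homozygous(self) -> bool:
        return bool(np.all(self.haplotypes[:, 0] == self.haplotypes[:, 1]))


class Population:
    """A cohort of individuals sharing one map and trait architecture.

    Stores haplotypes as a dense ``(N, P, 2)`` uint8 array; per-individual
    views are materialized on demand.  Vectorized accessors (``dose``,
    ``rc``, ``vb``, ``positive_mask``, ``successful_mask``) back the
    selection strategies.
    """

    def __init__(
        self,
        haps: np.ndarray,
        ids: Sequence[str],
        generation: int = 0,
        parent_a: Optional[Sequence[str]] = None,
        parent_b: Optional[Sequence[str]] = None,
        cross_type: Optional[Sequence[str]] = None,
    ):
        self.haps = np.ascontiguousarray(haps, dtype=np.uint8)
        if self.haps.ndim != 3 or self.haps.shape[2] != 2:
            raise ValueError("haps must have shape (N, P, 2)")
        self.ids = list(ids)
        if len(self.ids) != self.haps.shape[0]:
            raise ValueError("ids length must match N")
        self.generation = int(generation)
        self.parent_a = list(parent_a) if parent_a is not None else [None] * len(self.ids)
        self.parent_b = list(parent_b) if parent_b is not None else [None] * len(self.ids)
        self.cross_type = list(cross_type) if cross_type is not None else [None] * len(self.ids)

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual], generation: int = 0) -> "Population":
        inds = list(individuals)
        if not inds:
            raise ValueError("empty population")
        P = inds[0].n_markers
        if any(i.n_markers != P for i in inds):
            raise ValueError("all individuals must share the same marker count")
        haps = np.stack([i.haplotypes for i in inds])
        pop = cls(haps, [i.id for i in inds], generation=generation)
        for k, ind in enumerate(inds):
            if ind.pedigree is not None:
                pop.parent_a[k] = ind.pedigree.parent_a
                pop.parent_b[k] = ind.pedigree.parent_b
                pop.cross_type[k] = ind.pedigree.cross_type
        return pop

    def __len__(self) -> int:
        return self.haps.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haps.shape[1]

    def individual(self, i: int) -> Individual:
        return Individual(
            id=self.ids[i],
            haplotypes=self.haps[i],
            pedigree=Pedigree(self.parent_a[i], self.parent_b[i], self.cross_type[i], self.generation),
        )

    def __iter__(self):
        return (self.individual(i) for i in range(len(self)))

    # -- vectorized quantities ------------------------------------------------

    def dose(self) -> np.ndarray:
        return self.haps.sum(axis=2, dtype=np.int16)

    def rc(self, arch: TraitArchitecture) -> np.ndarray:
        """Background recovery rate per individual."""
        _check_dims(self, arch)
        bg = self.dose()[:, arch.background_mask]
        return bg.sum(axis=1) / (bg.shape[1] * 2.0)

    def vb(self, arch: TraitArchitecture) -> np.ndarray:
        """Background GEBV per individual."""
        _check_dims(self, arch)
        bg = self.dose()[:, arch.background_mask]
        return bg @ arch.background_effects

    def positive_mask(self, arch: TraitArchitecture) -> np.ndarray:
        """At least one favorable allele at every target locus."""
        _check_dims(self, arch)
        return (self.dose()[:, arch.target_loci] >= 1).all(axis=1)

    def successful_mask(self, arch: TraitArchitecture) -> np.ndarray:
        """Homozygous favorable at every target locus and RC >= rc_goal."""
        _check_dims(self, arch)
        fixed = (self.dose()[:, arch.target_loci] == 2).all(axis=1)
        return fixed & (self.rc(arch) >= arch.rc_goal)


def _check_dims(obj, arch: TraitArchitecture):
    P = obj.n_markers if not isinstance(obj, np.ndarray) else obj.shape[-2]
    if P != arch.n_markers:
        raise ValueError(
            f"marker count mismatch: haplotypes have {P}, effects have {arch.n_markers}"
        )


# -- scalar operations --------------------------------------------------------


def background_recovery_rate(ind: Individual, arch: TraitArchitecture) -> float:
    """Fraction of favorable alleles over the background loci (in [0, 1])."""
    _check_dims(ind, arch)
    bg = ind.dose()[arch.background_mask]
    return float(bg.sum()) / (len(bg) * 2.0)


def genetic_potential(a: Individual, b: Individual, loci) -> float:
    """Fraction of ``loci`` at which ``a`` and ``b`` jointly carry >= 1 favorable allele.

    Symmetric in its two parents; ``loci`` must be nonempty.
    """
    loci = np.asarray(list(loci) if not isinstance(loci, np.ndarray) else loci, dtype=int)
    if loci.size == 0:
        raise ValueError("locus set must be nonempty")
    joint = a.dose()[loci] + b.dose()[loci]
    return float(np.mean(joint >= 1))


def background_gebv(ind: Individual, arch: TraitArchitecture) -> float:
    """Effect-weighted favorable-allele count over the background loci (VB)."""
    _check_dims(ind, arch)
    return float(ind.dose()[arch.background_mask] @ arch.background_effects)


def is_positive(ind: Individual, arch: TraitArchitecture) -> bool:
    """True iff the individual has >= 1 favorable allele at every target locus."""
    return bool(np.all(ind.dose()[arch.target_loci] >= 1))


def is_successful(ind: Individual, arch: TraitArchitecture) -> bool:
    """Homozygous favorable at all target loci with RC >= rc_goal."""
    fixed = bool(np.all(ind.dose()[arch.target_loci] == 2))
    return fixed and background_recovery_rate(ind, arch) >= arch.rc_goal
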