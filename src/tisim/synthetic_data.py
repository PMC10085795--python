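"""Synthetic founder panels with the structure of a maize introgression study.

The generator emulates the standard setup this simulator targets: a few
hundred SNPs spread over 10 chromosomes proportionally to chromosome
length, three major-QTL target loci on distinct chromosomes, a panel of
fully inbred donor lines homozygous favorable at every target locus, and a
recurrent parent favorable at every background locus but not at the
targets.  Donor background alleles are i.i.d. Bernoulli draws, and allele
effects follow a heavy-tailed nonnegative (exponential) distribution with
the target-locus effects set largest — mimicking the sparse output of a
Bayesian whole-genome regression without estimating anything from data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Tuple

import numpy as np

from .genetics_core import GeneticMap, Individual, TraitArchitecture

__all__ = ["SyntheticSpec", "maize_like_preset", "micro_preset", "generate_panel", "write_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic founder panel."""

    n_chromosomes: int = 10
    markers_total: int = 390
    chromosome_length_cM: float = 150.0
    n_donors: int = 90
    target_chromosomes: Tuple[int, ...] = (3, 5, 8)
    donor_bg_freq: float = 0.5
    donor_heterozygosity: float = 0.0
    effect_scale: float = 1.0
    rc_goal: float = 0.96
    seed: int = 2023

    def __post_init__(self):
        if len(set(self.target_chromosomes)) != len(self.target_chromosomes):
            raise ValueError("target loci must be on distinct chromosomes")
        if len(self.target_chromosomes) > self.n_chromosomes:
            raise ValueError("more target loci than chromosomes")
        if not 0 <= self.donor_bg_freq <= 1:
            raise ValueError("donor background allele frequency must lie in [0, 1]")


def maize_like_preset(**overrides) -> SyntheticSpec:
    """The maize-like default: 390 SNPs / 10 chromosomes, 90 donors,
    targets on chromosomes 3, 5 and 8."""
    return replace(SyntheticSpec(), **overrides)


def micro_preset(**overrides) -> SyntheticSpec:
    """Tiny 2-chromosome, 12-marker panel within the enumeration oracle's reach."""
    spec = SyntheticSpec(
        n_chromosomes=2,
        markers_total=12,
        chromosome_length_cM=80.0,
        n_donors=6,
        target_chromosomes=(1, 2),
        seed=7,
    )
    return replace(spec, **overrides)


def generate_panel(spec: SyntheticSpec):
    """Build (donors, recurrent parent, genetic map, trait architecture).

    Everything is deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.full(spec.n_chromosomes, float(spec.chromosome_length_cM))
    # markers proportional to chromosome length (largest-remainder rounding)
    raw = spec.markers_total * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: spec.markers_total - counts.sum()]:
        counts[i] += 1
    chroms, pos = [], []
    for c in range(spec.n_chromosomes):
        chroms.append(np.full(counts[c], c + 1))
        pos.append(np.sort(rng.uniform(0, lengths[c], counts[c])))
    chrom = np.concatenate(chroms)
    position = np.concatenate(pos)
    P = spec.markers_total
    marker_ids = np.array([f"m{c}_{k}" for c, k in zip(chrom, _within_index(chrom))])
    gmap = GeneticMap(marker_ids, chrom, position)

    # target locus: the median marker of each designated chromosome
    targets = []
    for c in spec.target_chromosomes:
        idx = np.flatnonzero(gmap.chromosome == c)
        if idx.size == 0:
            raise ValueError(f"chromosome {c} has no markers")
        targets.append(int(idx[len(idx) // 2]))
    targets = np.array(sorted(targets))

    effects = rng.exponential(spec.effect_scale, size=P)
    effects[targets] = effects.max() * 1.5  # major QTL carry the largest effects
    arch = TraitArchitecture(target_loci=targets, effects=effects, rc_goal=spec.rc_goal)

    bg = arch.background_mask
    donors = []
    for d in range(spec.n_donors):
        hap = np.zeros((P, 2), dtype=np.uint8)
        draw = (rng.random(int(bg.sum())) < spec.donor_bg_freq).astype(np.uint8)
        hap[bg, 0] = draw
        hap[bg, 1] = draw
        if spec.donor_heterozygosity > 0:
            het = rng.random(int(bg.sum())) < spec.donor_heterozygosity
            hap[bg, 1] = np.where(het, 1 - hap[bg, 1], hap[bg, 1])
        hap[targets] = 1
        donors.append(Individual(id=f"D{d:03d}", haplotypes=hap))

    rp_hap = np.ones((P, 2), dtype=np.uint8)
    rp_hap[targets] = 0
    rp = Individual(id="RP", haplotypes=rp_hap)
    return donors, rp, gmap, arch


def _within_index(chrom: np.ndarray) -> np.ndarray:
    out = np.zeros(len(chrom), dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        out[idx] = np.arange(len(idx))
    return out


def write_fixture(spec: SyntheticSpec, outdir) -> dict:
    """Generate a panel and write it as the plain-text fixture directory."""
    from . import io as tio

    donors, rp, gmap, arch = generate_panel(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / "map.tsv",
        "effects": outdir / "effects.csv",
        "haplotypes": outdir / "haplotypes.csv",
        "arch": outdir / "architecture.yaml",
    }
    tio.write_map(gmap, paths["map"])
    tio.write_effects(gmap, arch, paths["effects"])
    tio.write_haplotypes([rp] + donors, gmap, paths["haplotypes"])
    tio.write_architecture(gmap, arch, rp.id, paths["arch"])
    return paths
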