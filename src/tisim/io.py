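"""File readers and writers for panels, configurations and program records.

Formats (all plain text):

* genetic map — tab-delimited ``marker  chrom  pos_cM`` with a header;
* allele effects — CSV ``marker,effect,favorable_allele``; the polarity
  column says which input allele is favorable, and haplotypes are recoded
  on read so that 1 always means favorable;
* haplotypes — wide CSV with a ``marker`` column and two columns
  ``<id>_hap1`` / ``<id>_hap2`` per individual (0/1 values); a phased VCF
  (``|``-separated GT) is accepted as an alternative;
* trait architecture — YAML naming the target markers, the recovery-rate
  goal and the recurrent parent's id;
* program records — JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genetics_core import GeneticMap, Individual, TraitArchitecture
from .pipeline import ProgramRecord

__all__ = [
    "read_map",
    "write_map",
    "read_effects",
    "write_effects",
    "read_haplotypes",
    "write_haplotypes",
    "read_phased_vcf",
    "read_architecture",
    "write_architecture",
    "read_panel",
    "write_records",
    "read_records",
]


def read_map(path) -> GeneticMap:
    table = pd.read_csv(path, sep="\t")
    return GeneticMap.from_table(table)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_table().to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"marker", "effect", "favorable_allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"effects file needs columns {sorted(required)}")
    if (df["effect"] < 0).any():
        raise ValueError("allele effects must be nonnegative")
    if not df["favorable_allele"].isin([0, 1]).all():
        raise ValueError("favorable_allele must be 0 or 1")
    return df


def write_effects(gmap: GeneticMap, arch: TraitArchitecture, path) -> None:
    pd.DataFrame(
        {
            "marker": gmap.marker_ids,
            "effect": arch.effects,
            "favorable_allele": np.ones(gmap.n_markers, dtype=int),
        }
    ).to_csv(path, index=False)


def read_haplotypes(path, gmap: GeneticMap, polarity: np.ndarray = None) -> List[Individual]:
    """Read the wide haplotype CSV; optionally recode polarity (1 = favorable)."""
    df = pd.read_csv(path)
    if "marker" not in df.columns:
        raise ValueError("haplotype file needs a 'marker' column")
    if list(df["marker"]) != list(gmap.marker_ids):
        raise ValueError("haplotype markers do not match the genetic map (same order required)")
    cols = [c for c in df.columns if c != "marker"]
    ids = []
    for c in cols:
        if not (c.endswith("_hap1") or c.endswith("_hap2")):
            raise ValueError(f"unexpected haplotype column {c!r}")
    seen = {}
    for c in cols:
        seen.setdefault(c.rsplit("_hap", 1)[0], []).append(c)
    individuals = []
    for ind_id, pair in seen.items():
        if len(pair) != 2:
            raise ValueError(f"individual {ind_id!r} must have exactly 2 haplotype columns")
        h = df[[f"{ind_id}_hap1", f"{ind_id}_hap2"]].to_numpy()
        if not np.isin(h, [0, 1]).all():
            raise ValueError(f"haplotype values for {ind_id!r} must be 0/1")
        h = h.astype(np.uint8)
        if polarity is not None:
            flip = polarity == 0
            h[flip] = 1 - h[flip]
        individuals.append(Individual(id=ind_id, haplotypes=h))
    return individuals


def write_haplotypes(individuals: Sequence[Individual], gmap: GeneticMap, path) -> None:
    data = {"marker": gmap.marker_ids}
    for ind in individuals:
        data[f"{ind.id}_hap1"] = ind.haplotypes[:, 0]
        data[f"{ind.id}_hap2"] = ind.haplotypes[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_phased_vcf(path, gmap: GeneticMap, polarity: np.ndarray = None) -> List[Individual]:
    """Read phased genotypes from a VCF; unphased or missing GTs are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = vcf.samples
    rows = []
    markers = []
    for var in vcf:
        markers.append(var.ID)
        g = np.asarray(var.genotypes)  # (n_samples, 3): a, b, phased
        if np.any(g[:, :2] < 0):
            raise ValueError(f"missing genotype at {var.ID}; phased non-missing GT required")
        if not np.all(g[:, 2]):
            raise ValueError(f"unphased genotype at {var.ID}; phased GT ('|') required")
        rows.append(g[:, :2])
    if markers != list(gmap.marker_ids):
        raise ValueError("VCF markers do not match the genetic map (same order required)")
    geno = np.stack(rows)  # (P, n_samples, 2)
    if polarity is not None:
        flip = polarity == 0
        geno[flip] = 1 - geno[flip]
    return [
        Individual(id=ids[s], haplotypes=geno[:, s, :].astype(np.uint8))
        for s in range(len(ids))
    ]


def write_architecture(gmap: GeneticMap, arch: TraitArchitecture, rp_id: str, path) -> None:
    doc = {
        "target_markers": [str(gmap.marker_ids[i]) for i in arch.target_loci],
        "rc_goal": float(arch.rc_goal),
        "rp_id": rp_id,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_architecture(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("target_markers", "rc_goal", "rp_id"):
        if key not in doc:
            raise ValueError(f"architecture file missing {key!r}")
    return doc


def read_panel(directory) -> Tuple[List[Individual], Individual, GeneticMap, TraitArchitecture]:
    """Load a fixture directory into a validated in-memory panel.

    Returns (donors, recurrent parent, map, architecture).
    """
    d = Path(directory)
    gmap = read_map(d / "map.tsv")
    eff = read_effects(d / "effects.csv")
    missing = set(gmap.marker_ids) - set(eff["marker"])
    if missing:
        raise ValueError(f"effects file missing markers: {sorted(missing)[:5]}")
    eff = eff.set_index("marker").loc[list(gmap.marker_ids)]
    polarity = eff["favorable_allele"].to_numpy()
    vcf_path = d / "haplotypes.vcf"
    if vcf_path.exists():
        individuals = read_phased_vcf(vcf_path, gmap, polarity)
    else:
        individuals = read_haplotypes(d / "haplotypes.csv", gmap, polarity)
    doc = read_architecture(d / "architecture.yaml")
    name_to_idx = {m: i for i, m in enumerate(gmap.marker_ids)}
    try:
        targets = [name_to_idx[m] for m in doc["target_markers"]]
    except KeyError as exc:
        raise ValueError(f"unknown target marker {exc.args[0]!r}") from None
    arch = TraitArchitecture(
        target_loci=np.array(targets),
        effects=eff["effect"].to_numpy(),
        rc_goal=float(doc["rc_goal"]),
    )
    rp = next((i for i in individuals if i.id == doc["rp_id"]), None)
    if rp is None:
        raise ValueError(f"recurrent parent {doc['rp_id']!r} not found in haplotypes")
    donors = [i for i in individuals if i.id != doc["rp_id"]]
    return donors, rp, gmap, arch


def write_records(records: Sequence[ProgramRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_records(path) -> List[ProgramRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            doc["cross_fractions"] = {
                int(k): v for k, v in doc.get("cross_fractions", {}).items()
            }
            records.append(ProgramRecord(**doc))
    return records
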