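"""Aggregate program records into outcome tables and diagnostics.

The headline summary is the distribution of *successful generations* per
(strategy, resource level, recovery-rate goal) group, the proportion of
programs succeeding by generation 5, and its standard error under the
sample-proportion convention ``sqrt(p (1 - p) / (n - 1))`` — the convention
that reproduces the parenthesized values of the study's summary table.
A second diagnostic reports the fractions of backcross / intercross / self
crosses chosen per selection generation.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .pipeline import ProgramRecord

__all__ = ["proportion_se", "aggregate", "crosstype_fractions", "success_by_generation"]

SUCCESS_GENERATION = 5


def proportion_se(successes: int, n: int) -> float:
    """Standard error of a sample proportion, ``sqrt(p (1 - p) / (n - 1))``."""
    if n < 2:
        raise ValueError("need n >= 2 for a proportion standard error")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p = successes / n
    return math.sqrt(p * (1.0 - p) / (n - 1))


def _key(rec: ProgramRecord):
    return (rec.strategy, rec.level, rec.rc_goal)


def aggregate(records: Sequence[ProgramRecord]) -> pd.DataFrame:
    """Outcome table keyed by (strategy, level, rc_goal).

    Columns: per-generation success counts ``gen4 .. gen<deadline>``,
    ``fail``, ``n``, ``success_by_g5`` (proportion) and ``se_g5``.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    rows = []
    groups: dict = {}
    for rec in records:
        groups.setdefault(_key(rec), []).append(rec)
    for key in sorted(groups):
        recs = groups[key]
        deadlines = {r.deadline for r in recs}
        if len(deadlines) != 1:
            raise ValueError(f"mixed deadlines within group {key}")
        deadline = deadlines.pop()
        n = len(recs)
        counts = {f"gen{g}": 0 for g in range(4, deadline + 1)}
        fail = 0
        for r in recs:
            if r.successful_generation is None:
                fail += 1
            else:
                counts[f"gen{r.successful_generation}"] += 1
        successes = sum(
            counts[f"gen{g}"] for g in range(4, min(SUCCESS_GENERATION, deadline) + 1)
        )
        rows.append(
            {
                "strategy": key[0],
                "level": key[1],
                "rc_goal": key[2],
                **counts,
                "fail": fail,
                "n": n,
                "success_by_g5": successes / n,
                "se_g5": proportion_se(successes, n) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def success_by_generation(records: Sequence[ProgramRecord], generation: int = SUCCESS_GENERATION) -> float:
    """Proportion of records succeeding at or before ``generation``."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    ok = sum(
        1
        for r in records
        if r.successful_generation is not None and r.successful_generation <= generation
    )
    return ok / len(records)


def crosstype_fractions(records: Sequence[ProgramRecord]) -> pd.DataFrame:
    """Mean backcross/intercross/self fractions per (strategy, level, generation)."""
    rows = []
    for rec in records:
        for t, fr in rec.cross_fractions.items():
            rows.append(
                {
                    "strategy": rec.strategy,
                    "level": rec.level,
                    "generation": int(t),
                    **{c: fr.get(c, 0.0) for c in ("backcross", "intercross", "self")},
                }
            )
    if not rows:
        raise ValueError("records carry no cross-type information")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["strategy", "level", "generation"], as_index=False)[
            ["backcross", "intercross", "self"]
        ].mean()
    )
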