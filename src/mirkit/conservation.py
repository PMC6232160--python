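"""Conserved-versus-novel calls for predicted miRNA targets.

Each predicted target is locally aligned against per-species sets of known
target sequences; a hit with alignment score strictly greater than 50 and
query coverage strictly greater than 50 percent makes the target a conserved
homolog in that species, otherwise it is a novel target.  "Score" is the raw
local alignment score (configurable).  The per-family summary mirrors the
usual conserved/novel target table: per-species conserved counts, a novel
column, totals, and the conserved percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .homology import BLASTN_SCORING, local_align
from .seqio import SequenceRecord


@dataclass
class ConservationCall:
    target_id: str
    family: str
    status: str  # conserved | novel
    best_species: Optional[str]
    best_score: float
    best_coverage: float  # % of the target covered by the alignment
    per_species: dict = field(default_factory=dict)  # species -> (score, cov, passes)


def classify_conserved(
    target: SequenceRecord,
    homolog_sets: dict[str, Sequence[SequenceRecord]],
    family: str = "",
    score_gt: float = 50.0,
    coverage_gt: float = 50.0,
    scoring: dict = BLASTN_SCORING,
) -> ConservationCall:
    """Call one target conserved or novel against all species' sets.

    Both thresholds are strict inequalities (score 50 exactly -> novel).
    The call is invariant to species ordering: the best species is chosen by
    (score, coverage), ties broken by species name.
    """
    if not target.sequence:
        raise ValueError("empty target sequence")
    per_species: dict[str, tuple[float, float, bool]] = {}
    for sp in sorted(homolog_sets):
        best_score, best_cov = 0.0, 0.0
        for hom in homolog_sets[sp]:
            hit = local_align(
                target.sequence, hom.sequence, scoring,
                query_id=target.id, subject_id=hom.id,
            )
            if hit is None:
                continue
            cov = 100.0 * (hit.query_end - hit.query_start + 1) / len(target.sequence)
            if (hit.score, cov) > (best_score, best_cov):
                best_score, best_cov = hit.score, cov
        per_species[sp] = (best_score, best_cov, best_score > score_gt and best_cov > coverage_gt)

    passing = [(s, v) for s, v in per_species.items() if v[2]]
    if passing:
        best_sp, (bs, bc, _) = max(passing, key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
        return ConservationCall(target.id, family, "conserved", best_sp, bs, bc, per_species)
    if per_species:
        best_sp, (bs, bc, _) = max(per_species.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
    else:
        best_sp, bs, bc = None, 0.0, 0.0
    return ConservationCall(target.id, family, "novel", best_sp, bs, bc, per_species)


def summarize_by_family(calls: Sequence[ConservationCall]) -> dict:
    """Family x species conserved counts, novel counts, totals, percentage."""
    species = sorted({sp for c in calls for sp in c.per_species})
    rows: dict[str, dict] = {}
    for c in calls:
        row = rows.setdefault(
            c.family, {**{sp: 0 for sp in species}, "conserved": 0, "novel": 0}
        )
        if c.status == "conserved":
            row["conserved"] += 1
            for sp in species:
                if c.per_species[sp][2]:
                    row[sp] += 1
        else:
            row["novel"] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    totals = table.sum(axis=0)
    conserved_total = int(totals.get("conserved", 0))
    novel_total = int(totals.get("novel", 0))
    denom = conserved_total + novel_total
    return {
        "table": table,
        "totals": totals,
        "conserved_total": conserved_total,
        "novel_total": novel_total,
        "conserved_percent": 100.0 * conserved_total / denom if denom else float("nan"),
    }


def family_count_totals(per_family: pd.DataFrame, conserved_col: str, novel_col: str) -> dict:
    """Column totals and conserved percentage from a printed-style per-family
    count table (rows = families, columns = per-species conserved counts and
    a novel-targets column)."""
    totals = per_family.sum(axis=0, numeric_only=True)
    conserved_total = int(totals[conserved_col])
    novel_total = int(totals[novel_col])
    pct = 100.0 * conserved_total / (conserved_total + novel_total)
    return {
        "totals": totals.to_dict(),
        "conserved_total": conserved_total,
        "novel_total": novel_total,
        "conserved_percent": pct,
    }
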