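"""Locus clustering, naming, tissue tallies and nucleotide composition.

Accepted precursor candidates differing by fewer than two whole-length
mismatches are alleles of the same tentative locus (single-linkage, so the
partition is independent of input order).  Loci are renamed after the
closest reference (rice) locus; tissue occupancy and position-specific base
composition of the mature set round out the catalogue description.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .homology import whole_length_mismatches
from .seqio import TISSUES, parse_mirna_name

TISSUE_SUFFIX = {"bud": "b", "culm": "c", "leaf": "l", "root": "r", "unknown": "u"}


@dataclass
class CandidateMember:
    """One accepted precursor candidate entering locus clustering."""

    candidate_id: str
    precursor_sequence: str
    mature_sequence: str
    family: str
    reference_name: str  # best reference (rice) precursor hit
    tissue: str = "unknown"


@dataclass
class MiRNALocus:
    locus_id: int
    family: str
    rice_best_hit: Optional[str]
    members: list = field(default_factory=list)  # CandidateMember

    @property
    def tissues(self) -> set:
        return {m.tissue for m in self.members}


def cluster_loci(
    candidates: Sequence[CandidateMember], mismatch_lt: int = 2
) -> list[MiRNALocus]:
    """Single-linkage clustering of candidates into tentative loci.

    Two candidates are linked when their precursors differ by fewer than
    ``mismatch_lt`` whole-length mismatches (default: < 2, i.e. at most one).
    Locus ids follow the first member's input order, so the partition is
    stable for a given input set regardless of ordering.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    order = sorted(range(n), key=lambda i: candidates[i].candidate_id)
    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            if (
                whole_length_mismatches(
                    candidates[i].precursor_sequence, candidates[j].precursor_sequence
                )
                < mismatch_lt
            ):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in sorted(range(n), key=lambda i: candidates[i].candidate_id):
        groups.setdefault(find(i), []).append(i)
    loci = []
    for k, (root, idxs) in enumerate(
        sorted(groups.items(), key=lambda kv: candidates[kv[1][0]].candidate_id), start=1
    ):
        members = [candidates[i] for i in idxs]
        fams = {m.family for m in members}
        rice = members[0].reference_name
        loci.append(MiRNALocus(k, sorted(fams)[0], rice, members))
    return loci


def assign_names(
    locus: MiRNALocus, prefix: str = "Ado", tissue_suffix: dict = TISSUE_SUFFIX
) -> dict[str, str]:
    """Name every member of a locus after its closest rice locus.

    Pattern: ``{prefix}-{rice family+variant}-{locus index}{allele letter}_
    {tissue initial}`` (e.g. Ado-MIR444d-2c_b = locus 2, allele c, bud).
    Members are lettered a, b, c... in candidate-id order, so names are
    deterministic.  A locus without a rice hit is named by family only, with
    a warning.
    """
    if locus.rice_best_hit:
        info = parse_mirna_name(locus.rice_best_hit)
        stem = f"{info['family']}{info['variant']}"
    else:
        warnings.warn(f"locus {locus.locus_id} has no rice best hit; family-only name")
        stem = locus.family
    names = {}
    for k, member in enumerate(sorted(locus.members, key=lambda m: m.candidate_id)):
        allele = chr(ord("a") + k)
        suffix = tissue_suffix.get(member.tissue, "u")
        names[member.candidate_id] = f"{prefix}-{stem}-{locus.locus_id}{allele}_{suffix}"
    return names


def tissue_tally(loci: Sequence[MiRNALocus]) -> dict:
    """Counts and percentages of mature miRNAs per tissue, plus the
    family x tissue occupancy matrix."""
    counts = {t: 0 for t in TISSUES}
    fam_rows: dict[str, dict] = {}
    total = 0
    for locus in loci:
        for m in locus.members:
            if m.tissue in counts:
                counts[m.tissue] += 1
                total += 1
            fam_rows.setdefault(locus.family, {t: 0 for t in TISSUES})
            if m.tissue in TISSUES:
                fam_rows[locus.family][m.tissue] += 1
    percents = {t: (100.0 * c / total if total else 0.0) for t, c in counts.items()}
    matrix = pd.DataFrame.from_dict(fam_rows, orient="index").fillna(0).astype(int)
    matrix = matrix.sort_index()
    return {"counts": counts, "percent": percents, "by_family": matrix, "total": total}


def locus_table(loci: Sequence[MiRNALocus]) -> pd.DataFrame:
    """Per-family locus table: number of loci and member counts per locus."""
    rows = []
    fam_groups: dict[str, list[MiRNALocus]] = {}
    for locus in loci:
        fam_groups.setdefault(locus.family, []).append(locus)
    for fam in sorted(fam_groups):
        group = fam_groups[fam]
        rows.append(
            {
                "family": fam,
                "n_loci": len(group),
                "n_members": sum(len(l.members) for l in group),
                "members_per_locus": ",".join(str(len(l.members)) for l in group),
            }
        )
    return pd.DataFrame(rows)


def locus_table_total(per_family_locus_counts: dict[str, list[int]]) -> int:
    """Total locus count from per-family lists of per-rice-locus counts.

    The per-family entry lists, for each reference locus, how many distinct
    loci were inferred in the studied species; the catalogue total is the
    grand sum.
    """
    return sum(sum(v) for v in per_family_locus_counts.values())


# ---------------------------------------------------------------------------
# composition profiling


@dataclass
class CompositionProfile:
    overall: dict  # base -> %
    positional: pd.DataFrame  # index position (1-based), columns A/C/G/U, %
    n_sequences: int
    max_length: int


def composition_profile(matures: Sequence[str]) -> CompositionProfile:
    """Overall and position-specific base frequencies (percent).

    Positions beyond a sequence's length are excluded from that column's
    denominator, so every positional column sums to 100 over the bases
    present there.
    """
    seqs = [getattr(s, "sequence", s) for s in matures]
    if not seqs:
        raise ValueError("no sequences to profile")
    max_len = max(len(s) for s in seqs)
    bases = "ACGU"
    overall_counts = {b: 0 for b in bases}
    pos_counts = [{b: 0 for b in bases} for _ in range(max_len)]
    pos_totals = [0] * max_len
    total = 0
    for s in seqs:
        for i, c in enumerate(s):
            if c in overall_counts:
                overall_counts[c] += 1
                pos_counts[i][c] += 1
                pos_totals[i] += 1
                total += 1
    overall = {b: 100.0 * overall_counts[b] / total for b in bases}
    rows = []
    for i in range(max_len):
        denom = pos_totals[i] or 1
        rows.append({b: 100.0 * pos_counts[i][b] / denom for b in bases})
    positional = pd.DataFrame(rows, index=range(1, max_len + 1))
    return CompositionProfile(overall, positional, len(seqs), max_len)


def compare_profiles(a: CompositionProfile, b: CompositionProfile) -> dict:
    """Difference tables (a - b, percentage points) and per-position dominant
    bases of each profile."""
    overall_diff = {base: a.overall[base] - b.overall[base] for base in "ACGU"}
    pos = a.positional.sub(b.positional, fill_value=0.0)
    dominant_a = a.positional.idxmax(axis=1)
    dominant_b = b.positional.idxmax(axis=1)
    return {
        "overall_diff": overall_diff,
        "positional_diff": pos,
        "dominant_a": dominant_a,
        "dominant_b": dominant_b,
    }


def catalogue_statistics(matures: Sequence[str], precursors: Sequence[str]) -> dict:
    """Headline statistics of a miRNA catalogue.

    Mature length distribution (percent per length), mean precursor length,
    overall base percentages, GC%, and the fraction of matures starting with
    uridine at the 5' end.
    """
    mats = [getattr(s, "sequence", s) for s in matures]
    precs = [getattr(s, "sequence", s) for s in precursors]
    lengths = pd.Series([len(m) for m in mats])
    length_pct = (lengths.value_counts(normalize=True) * 100).sort_index().to_dict()
    prof = composition_profile(mats)
    return {
        "n_matures": len(mats),
        "mature_length_percent": length_pct,
        "mean_precursor_length": (
            sum(len(p) for p in precs) / len(precs) if precs else float("nan")
        ),
        "overall_percent": prof.overall,
        "gc_percent": prof.overall["G"] + prof.overall["C"],
        "five_prime_u_percent": 100.0 * sum(m[0] == "U" for m in mats) / len(mats),
    }
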