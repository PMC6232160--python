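"""Precursor folding and the six-criterion hairpin filter.

A candidate pre-miRNA must (1) carry a mature of 19-25 nt, (2) differ from
the reference mature by at most two substitutions, (3) place the mature on a
single arm of the stem-loop, (4) pair the mature against its star with at
most five mismatches, (5) have an A+U content between 30 and 70 percent, and
(6) fold with a minimal folding energy index MFEI <= -0.85 (inclusive).

MFEI = AMFE / GC%, AMFE = MFE / length * 100, with GC% expressed as a
percentage (50, not 0.5); empirically MFEI separates pre-miRNAs (around -1.0)
from tRNA/rRNA/mRNA fragments (around -0.6).

Two folding engines implement a common contract: the thermodynamic engine
(ViennaRNA minimum free energy) is the default; a built-in Nussinov-style
base-pair-maximisation engine (minimum loop 3; AU/GC/GU pairs; pseudo-energy
-1 kcal/mol per pair) provides an engine-independent reference for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import edlib

from .seqio import UNAMBIGUOUS_RNA, SequenceRecord

CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    dotbracket: str
    mfe: float  # kcal/mol, <= 0
    engine: str

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")
        if self.dotbracket.count("(") != self.dotbracket.count(")"):
            raise ValueError("unbalanced dot-bracket string")

    def to_vienna(self) -> str:
        """Vienna text convention: 'sequence\\nstructure (mfe)'."""
        return f"{self.sequence}\n{self.dotbracket} ({self.mfe:.2f})"


@dataclass(frozen=True)
class HairpinMetrics:
    length: int
    gc_percent: float
    au_percent: float
    mfe: float
    amfe: float  # kcal/mol per 100 nt
    mfei: float  # AMFE / GC%


@dataclass(frozen=True)
class MatureSite:
    """Placement of a reference mature on a folded precursor (1-based closed)."""

    start: int
    end: int
    arm: str  # 5p | 3p | loop_spanning
    mismatches_to_reference: int
    duplex_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FilterReport:
    c1_length_ok: bool
    c2_ref_mismatch_ok: bool
    c3_single_arm_ok: bool
    c4_duplex_mismatch_ok: bool
    c5_au_content_ok: bool
    c6_mfei_ok: bool
    measured: dict = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return (
            self.c1_length_ok
            and self.c2_ref_mismatch_ok
            and self.c3_single_arm_ok
            and self.c4_duplex_mismatch_ok
            and self.c5_au_content_ok
            and self.c6_mfei_ok
        )

    def failed_criteria(self) -> list[str]:
        names = ["c1", "c2", "c3", "c4", "c5", "c6"]
        flags = [
            self.c1_length_ok,
            self.c2_ref_mismatch_ok,
            self.c3_single_arm_ok,
            self.c4_duplex_mismatch_ok,
            self.c5_au_content_ok,
            self.c6_mfei_ok,
        ]
        return [n for n, ok in zip(names, flags) if not ok]


# ---------------------------------------------------------------------------
# folding engines


def _fold_vienna(sequence: str) -> tuple[str, float]:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise FoldError("ViennaRNA python bindings unavailable (engine 'vienna')") from exc
    db, mfe = RNA.fold(sequence)
    return db, min(mfe, 0.0)


def _fold_nussinov(sequence: str) -> tuple[str, float]:
    """Base-pair maximisation with minimum loop length 3 (O(n^3) DP)."""
    n = len(sequence)
    pairable = [
        [(sequence[i], sequence[j]) in CANONICAL_PAIRS for j in range(n)] for i in range(n)
    ]
    N = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            if pairable[i][j]:
                inner = N[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i + MIN_LOOP + 1, j):
                if pairable[i][k]:
                    left = N[i + 1][k - 1] if i + 1 <= k - 1 else 0
                    best = max(best, left + 1 + N[k + 1][j])
            N[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if N[i][j] == N[i + 1][j]:
                i += 1
                continue
            if pairable[i][j] and N[i][j] == (N[i + 1][j - 1] if i + 1 <= j - 1 else 0) + 1:
                structure[i], structure[j] = "(", ")"
                i, j = i + 1, j - 1
                continue
            for k in range(i + MIN_LOOP + 1, j):
                left = N[i + 1][k - 1] if i + 1 <= k - 1 else 0
                if pairable[i][k] and N[i][j] == left + 1 + N[k + 1][j]:
                    structure[i], structure[k] = "(", ")"
                    traceback(i + 1, k - 1)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive
                i += 1

    traceback(0, n - 1)
    return "".join(structure), -float(N[0][n - 1])


_ENGINES = {"vienna": _fold_vienna, "nussinov": _fold_nussinov}


def fold(sequence: str, engine: str = "vienna") -> SecondaryStructure:
    """Fold an RNA sequence into its MFE (or max-pair) secondary structure.

    Ambiguity codes and sequences shorter than 10 nt are rejected.
    Deterministic: same sequence and engine give the same structure.
    """
    if len(sequence) < 10:
        raise FoldError(f"sequence too short to fold ({len(sequence)} nt < 10)")
    bad = set(sequence) - UNAMBIGUOUS_RNA
    if bad:
        raise FoldError(f"cannot fold sequence with ambiguity codes {sorted(bad)}")
    if engine not in _ENGINES:
        raise FoldError(f"unknown folding engine {engine!r}")
    db, mfe = _ENGINES[engine](sequence)
    return SecondaryStructure(sequence, db, mfe, engine)


def pair_table(dotbracket: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired."""
    partner = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(structure: SecondaryStructure) -> HairpinMetrics:
    """Length, GC%, AU%, AMFE and MFEI of a folded candidate."""
    seq = structure.sequence
    n = len(seq)
    gc = 100.0 * sum(seq.count(b) for b in "GC") / n
    au = 100.0 * sum(seq.count(b) for b in "AU") / n
    if gc == 0.0:
        raise ValueError("MFEI undefined for a sequence with zero GC content")
    amfe = structure.mfe / n * 100.0
    mfei = amfe / gc
    return HairpinMetrics(n, gc, au, structure.mfe, amfe, mfei)


# ---------------------------------------------------------------------------
# terminal loop / arm geometry


def hairpin_loops(partner: list[int]) -> list[tuple[int, int]]:
    """Closing pairs (i, j) of hairpin loops: pairs with nothing paired inside."""
    loops = []
    for i, j in enumerate(partner):
        if j > i:
            if all(partner[k] == -1 for k in range(i + 1, j)):
                loops.append((i, j))
    return loops


def _stem_pairs_of_loop(partner: list[int], loop: tuple[int, int]) -> int:
    """Number of pairs whose span encloses this hairpin loop and no other."""
    li, lj = loop
    loops = hairpin_loops(partner)
    count = 0
    for i, j in enumerate(partner):
        if j > i and i <= li and j >= lj:
            inside = [l for l in loops if i <= l[0] and l[1] <= j]
            if inside == [loop]:
                count += 1
    return count


def terminal_loop(structure: SecondaryStructure) -> Optional[tuple[int, int, bool]]:
    """Locate the terminal loop of the dominant hairpin.

    Returns (loop_start, loop_end, is_clean_hairpin) in 0-based indices of
    the unpaired loop run, or None when nothing pairs at all.  The dominant
    hairpin is the one whose stem holds the most base pairs;
    ``is_clean_hairpin`` is False when the structure branches (any pair
    enclosing two or more hairpin loops, i.e. a multiloop).
    """
    partner = pair_table(structure.dotbracket)
    loops = hairpin_loops(partner)
    if not loops:
        return None
    best = max(loops, key=lambda l: (_stem_pairs_of_loop(partner, l), -l[0]))
    multiloop = False
    for i, j in enumerate(partner):
        if j > i:
            inside = [l for l in loops if i <= l[0] and l[1] <= j]
            if len(inside) >= 2:
                multiloop = True
                break
    return best[0] + 1, best[1] - 1, not multiloop


# ---------------------------------------------------------------------------
# mature placement


def locate_mature(
    precursor: str,
    structure: SecondaryStructure,
    mature: str | SequenceRecord,
    max_mismatches: int = 5,
    count_gu_as_mismatch: bool = False,
) -> Optional[MatureSite]:
    """Place the best-matching window for a reference mature on the precursor.

    The window minimising whole-length mismatches (substitutions + indels,
    semi-global alignment) is found; ties are broken by fewer duplex
    mismatches, then by the 5'-most window.  Returns None when no window has
    <= ``max_mismatches`` mismatches (candidate unmappable).

    Duplex mismatches count mature positions that are unpaired in the folded
    structure or paired outside the opposite arm of the dominant hairpin;
    G:U wobbles count as paired unless ``count_gu_as_mismatch``.
    """
    mat = mature.sequence if isinstance(mature, SequenceRecord) else mature
    if not 19 <= len(mat) <= 25:
        raise ValueError(f"reference mature length {len(mat)} outside 19-25 nt")
    res = edlib.align(mat, precursor, mode="HW", task="locations", k=max_mismatches)
    if res["editDistance"] == -1:
        return None
    dist = res["editDistance"]
    locations = sorted(set(res["locations"]))

    tl = terminal_loop(structure)
    partner = pair_table(structure.dotbracket)

    def site_for(loc: tuple[int, int]) -> MatureSite:
        s, e = loc  # 0-based inclusive
        if tl is None:
            arm = "loop_spanning"
        else:
            loop_s, loop_e, clean = tl
            if not clean:
                arm = "loop_spanning"
            elif e < loop_s:
                arm = "5p"
            elif s > loop_e:
                arm = "3p"
            else:
                arm = "loop_spanning"
        dmm = _duplex_mismatches(precursor, partner, s, e, tl, count_gu_as_mismatch)
        return MatureSite(s + 1, e + 1, arm, dist, dmm)

    sites = [site_for(loc) for loc in locations]
    sites.sort(key=lambda st: (st.duplex_mismatches, st.start))
    return sites[0]


def locate_best_mature(
    precursor: str,
    structure: SecondaryStructure,
    matures: list,
    max_mismatches: int = 5,
    count_gu_as_mismatch: bool = False,
) -> Optional[MatureSite]:
    """Best placement across several reference matures (e.g. a family's).

    Candidates are compared against every known reference mature and the
    placement with the fewest mismatches wins (ties: fewer duplex
    mismatches, then 5'-most).
    """
    best: Optional[MatureSite] = None
    for mat in matures:
        site = locate_mature(precursor, structure, mat, max_mismatches, count_gu_as_mismatch)
        if site is None:
            continue
        key = (site.mismatches_to_reference, site.duplex_mismatches, site.start)
        if best is None or key < (best.mismatches_to_reference, best.duplex_mismatches, best.start):
            best = site
    return best


def _duplex_mismatches(
    seq: str,
    partner: list[int],
    s: int,
    e: int,
    tl: Optional[tuple[int, int, bool]],
    count_gu_as_mismatch: bool,
) -> int:
    if tl is None:
        return e - s + 1
    loop_s, loop_e, _ = tl
    mm = 0
    for k in range(s, e + 1):
        p = partner[k]
        if p == -1:
            mm += 1
            continue
        # partner must lie on the opposite side of the terminal loop
        same_side = (k < loop_s and p < loop_s) or (k > loop_e and p > loop_e)
        if same_side:
            mm += 1
            continue
        if count_gu_as_mismatch and (seq[k], seq[p]) in {("G", "U"), ("U", "G")}:
            mm += 1
    return mm


# ---------------------------------------------------------------------------
# the six criteria


@dataclass(frozen=True)
class CriteriaThresholds:
    mature_len_min: int = 19
    mature_len_max: int = 25
    ref_mismatch_max: int = 2
    duplex_mismatch_max: int = 5
    au_min: float = 30.0
    au_max: float = 70.0
    mfei_cutoff: float = -0.85  # inclusive


def evaluate_criteria(
    metrics: HairpinMetrics,
    site: Optional[MatureSite],
    mature_length: int,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> FilterReport:
    """Apply the six acceptance criteria; an unmappable site fails 2-4."""
    t = thresholds
    c1 = t.mature_len_min <= mature_length <= t.mature_len_max
    if site is None:
        c2 = c3 = c4 = False
        measured_site: dict = {"site": None}
    else:
        c2 = site.mismatches_to_reference <= t.ref_mismatch_max
        c3 = site.arm in ("5p", "3p")
        c4 = site.duplex_mismatches <= t.duplex_mismatch_max
        measured_site = {
            "ref_mismatches": site.mismatches_to_reference,
            "arm": site.arm,
            "duplex_mismatches": site.duplex_mismatches,
        }
    c5 = t.au_min <= metrics.au_percent <= t.au_max
    c6 = metrics.mfei <= t.mfei_cutoff
    measured = {
        "mature_length": mature_length,
        "au_percent": metrics.au_percent,
        "mfei": metrics.mfei,
        "mfe": metrics.mfe,
        "amfe": metrics.amfe,
        "length": metrics.length,
        **measured_site,
    }
    return FilterReport(c1, c2, c3, c4, c5, c6, measured)


# ---------------------------------------------------------------------------
# hairpin excision for homology-hit windows


def excise_precursor(
    window: str,
    mature_start: int,
    mature_end: int,
    engine: str = "vienna",
    max_span: int = 300,
    max_tries: int = 8,
) -> Optional[tuple[int, int, SecondaryStructure]]:
    """Trim a homology-hit window down to the stem-loop around the mature.

    The window is folded once; every base pair whose span encloses the mature
    interval (1-based, closed, on the window) proposes a precursor span.
    Candidate spans (capped at ``max_span`` nt) are each refolded and the
    clean single hairpin with the lowest folding-energy index (MFEI) wins:
    the boundary best supported by folding, mirroring how stem-loop excision
    tools trim a pri-miRNA window to its pre-miRNA.  Returns
    (start, end, structure) in window coordinates, or None when nothing
    encloses the mature.
    """
    try:
        full = fold(window, engine=engine)
    except FoldError:
        return None
    partner = pair_table(full.dotbracket)
    s0, e0 = mature_start - 1, mature_end - 1
    enclosing = [
        (i, j)
        for i, j in enumerate(partner)
        if j > i and i <= s0 and j >= e0 and (j - i + 1) <= max_span
    ]
    if not enclosing:
        return None
    enclosing.sort(key=lambda p: p[0])  # outermost first
    # thin the list so wide and narrow spans both get a chance
    step = max(1, len(enclosing) // max_tries)
    tried = enclosing[::step][:max_tries]
    best = None  # (mfei, span_len, start, end, structure)
    fallback = None
    for i, j in tried:
        sub = window[i : j + 1]
        if len(sub) < 10:
            continue
        try:
            st = fold(sub, engine=engine)
            mfei = compute_metrics(st).mfei
        except (FoldError, ValueError):
            continue
        tl = terminal_loop(st)
        if tl is not None and tl[2]:
            key = (mfei, j - i)
            if best is None or key < best[:2]:
                best = (mfei, j - i, i + 1, j + 1, st)
        elif fallback is None:
            fallback = (i + 1, j + 1, st)
    if best is not None:
        return best[2], best[3], best[4]
    return fallback
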