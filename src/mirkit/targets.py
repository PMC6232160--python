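"""miRNA target prediction by complementarity scoring.

A miRNA (5'->3') is aligned antiparallel against a candidate site on the
transcript and charged a cumulative penalty ("expectation", lower is better):
mismatch 1.0, G:U wobble 0.5, indel 2.0, with every penalty doubled in the
seed-proximal core (miRNA positions 2-13).  Two scoring modes mirror the two
widely used plant target predictors:

* ``psrnatarget_like`` - only the best 20-nt window of the miRNA is scored
  (complementarity scoring length, "hspsize"), reporting threshold
  expectation <= 3.0 (inclusive);
* ``targetfinder_like`` - the full miRNA is scored, reporting threshold
  score < 4.0 (strict).

Hits present in both modes at the same site are the consensus target set.
A hit whose core positions 10-11 pair (G:U counting as pairing) silences by
transcript cleavage, annotated opposite the bond between miRNA nt 10 and 11;
a mismatch or gap at position 10 or 11 marks translational inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .seqio import SequenceRecord

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "U"), ("U", "G")}

MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
INDEL_PENALTY = 2.0
CORE = (2, 13)  # doubled-penalty miRNA positions, 1-based closed
CORE_FACTOR = 2.0
HSP_SIZE = 20

PSR_EXPECTATION_MAX = 3.0  # inclusive
TF_SCORE_LT = 4.0  # strict

MODES = ("psrnatarget_like", "targetfinder_like")


def pair_class(mirna_base: str, target_base: str) -> str:
    if (mirna_base, target_base) in WC:
        return "match"
    if (mirna_base, target_base) in GU:
        return "gu"
    return "mismatch"


def position_weight(pos: int) -> float:
    return CORE_FACTOR if CORE[0] <= pos <= CORE[1] else 1.0


@dataclass(frozen=True)
class DuplexScore:
    """Scored miRNA/site duplex with per-position pairing states.

    ``per_position[i-1]`` is the state of miRNA position i (counted from the
    miRNA 5' end): match | gu | mismatch | gap | unscored.  ``pair_map``
    gives the 1-based site coordinate (site read 5'->3') opposite each
    miRNA position that faces a target base.
    """

    expectation: float
    per_position: tuple[str, ...]
    pair_map: dict = field(hash=False)
    mode: str
    window: tuple[int, int]  # scored miRNA positions, 1-based closed


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based closed, transcript coordinates
    site_end: int
    score: DuplexScore
    upe: Optional[float] = None
    inhibition: Optional[str] = None  # cleavage | translation
    cleavage_position: Optional[int] = None


@dataclass(frozen=True)
class ConsensusHit:
    """A (miRNA, transcript) pair confirmed by both scoring modes."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    psr_expectation: float
    tf_score: float
    inhibition: str
    cleavage_position: Optional[int]


# ---------------------------------------------------------------------------
# core alignment


def _align_window(mirna: str, first_pos: int, site_rev: str) -> tuple[float, list, list]:
    """Globally align a miRNA window against the reversed site.

    The miRNA window is consumed entirely; unconsumed site ends are free
    (semi-global on the target).  Returns (cost, states, pairs) where states
    are per window position and pairs index into ``site_rev`` (0-based, -1
    for a gap).  Deterministic traceback: pairing beats miRNA-gap beats
    target-insertion on ties.
    """
    I, J = len(mirna), len(site_rev)
    INF = math.inf
    D = [[INF] * (J + 1) for _ in range(I + 1)]
    for j in range(J + 1):
        D[0][j] = 0.0  # leading target overhang free
    for i in range(1, I + 1):
        pos = first_pos + i - 1
        w = position_weight(pos)
        gap_cost = INDEL_PENALTY * w
        ins_w = position_weight(min(pos + 1, first_pos + I - 1))
        row, prev = D[i], D[i - 1]
        mb = mirna[i - 1]
        row[0] = prev[0] + gap_cost
        for j in range(1, J + 1):
            cls = pair_class(mb, site_rev[j - 1])
            pc = 0.0 if cls == "match" else (GU_PENALTY if cls == "gu" else MISMATCH_PENALTY)
            best = prev[j - 1] + pc * w  # pair miRNA i with site j
            cand = prev[j] + gap_cost  # miRNA base unpaired
            if cand < best:
                best = cand
            if i < I:  # target bulge; with i == I trailing overhang is free
                cand = row[j - 1] + INDEL_PENALTY * ins_w
                if cand < best:
                    best = cand
            row[j] = best
    end_j = min(range(J + 1), key=lambda j: (D[I][j], -j))
    cost = D[I][end_j]

    # traceback
    states: list[str] = []
    pairs: list[int] = []
    i, j = I, end_j
    while i > 0:
        pos = first_pos + i - 1
        w = position_weight(pos)
        gap_cost = INDEL_PENALTY * w
        ins_w = position_weight(min(pos + 1, first_pos + I - 1))
        if j > 0:
            cls = pair_class(mirna[i - 1], site_rev[j - 1])
            pc = 0.0 if cls == "match" else (GU_PENALTY if cls == "gu" else MISMATCH_PENALTY)
            if math.isclose(D[i][j], D[i - 1][j - 1] + pc * w, abs_tol=1e-12):
                states.append(cls)
                pairs.append(j - 1)
                i, j = i - 1, j - 1
                continue
        if math.isclose(D[i][j], D[i - 1][j] + gap_cost, abs_tol=1e-12):
            states.append("gap")
            pairs.append(-1)
            i -= 1
            continue
        # target insertion
        j -= 1
    states.reverse()
    pairs.reverse()
    return cost, states, pairs


def score_duplex(
    mirna: str | SequenceRecord,
    site_sequence: str | SequenceRecord,
    mode: str = "targetfinder_like",
) -> DuplexScore:
    """Score the duplex of a miRNA against a candidate site (both 5'->3').

    The miRNA 5' end faces the site 3' end.  ``psrnatarget_like`` takes the
    best-scoring 20-nt miRNA window; ``targetfinder_like`` scores the whole
    miRNA.  The expectation equals the weighted sum of per-position
    penalties by construction.
    """
    m = mirna.sequence if isinstance(mirna, SequenceRecord) else mirna
    s = site_sequence.sequence if isinstance(site_sequence, SequenceRecord) else site_sequence
    if not 19 <= len(m) <= 25:
        raise ValueError(f"miRNA length {len(m)} outside 19-25 nt")
    if mode not in MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    site_rev = s[::-1]
    L = len(m)
    if mode == "targetfinder_like" or L <= HSP_SIZE:
        windows = [(1, L)]
    else:
        windows = [(a, a + HSP_SIZE - 1) for a in range(1, L - HSP_SIZE + 2)]

    best = None
    for a, b in windows:
        cost, states, pairs = _align_window(m[a - 1 : b], a, site_rev)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, states, pairs, (a, b))
    cost, states, pairs, window = best

    per_position = ["unscored"] * L
    pair_map: dict[int, int] = {}
    a, b = window
    for k, st in enumerate(states):
        pos = a + k
        per_position[pos - 1] = st
        if pairs[k] >= 0:
            pair_map[pos] = len(s) - pairs[k]  # back to 5'->3' site coordinate
    return DuplexScore(cost, tuple(per_position), pair_map, mode, window)


# ---------------------------------------------------------------------------
# transcript scanning


_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}
_PENALTY_LUT = np.ones((5, 5), dtype=float) * MISMATCH_PENALTY
for (x, y) in WC:
    _PENALTY_LUT[_BASE_INDEX[x], _BASE_INDEX[y]] = 0.0
for (x, y) in GU:
    _PENALTY_LUT[_BASE_INDEX[x], _BASE_INDEX[y]] = GU_PENALTY

_SCAN_MARGIN = 3.0  # rescoring margin over the reporting threshold


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def _ungapped_profile(m: str, t_codes: np.ndarray) -> np.ndarray:
    """pen[i, p] = penalty of miRNA position i+1 against the site starting at p."""
    L, n = len(m), len(t_codes)
    n_windows = n - L + 1
    if n_windows <= 0:
        return np.zeros((L, 0))
    pen = np.empty((L, n_windows))
    for i in range(L):
        w = position_weight(i + 1)
        # miRNA position i+1 faces transcript offset p + (L - 1 - i)
        tb = t_codes[L - 1 - i : L - 1 - i + n_windows]
        pen[i] = _PENALTY_LUT[_encode(m[i])[0], tb] * w
    return pen


def _window_min_costs(pen: np.ndarray, mode: str) -> np.ndarray:
    """Ungapped expectation per transcript start, minimised over hsp windows."""
    L = pen.shape[0]
    if mode == "targetfinder_like" or L <= HSP_SIZE:
        return pen.sum(axis=0)
    cum = np.vstack([np.zeros((1, pen.shape[1])), np.cumsum(pen, axis=0)])
    costs = [cum[a + HSP_SIZE] - cum[a] for a in range(L - HSP_SIZE + 1)]
    return np.min(costs, axis=0)


def default_threshold(mode: str) -> float:
    return PSR_EXPECTATION_MAX if mode == "psrnatarget_like" else TF_SCORE_LT


def _passes(cost: float, mode: str, threshold: float) -> bool:
    if mode == "psrnatarget_like":
        return cost <= threshold + 1e-12
    return cost < threshold - 1e-12


def scan_transcript(
    mirna: SequenceRecord,
    transcript,
    mode: str = "targetfinder_like",
    threshold: Optional[float] = None,
) -> list[TargetHit]:
    """All non-overlapping target sites of a miRNA on one transcript.

    Candidate starts are pre-screened with a vectorised ungapped scan (with a
    rescoring margin) and rescored exactly with the gapped duplex aligner;
    overlapping candidates are resolved left-to-right, keeping the local
    optimum.  Reportable gapped hits carry at most one indel (two indels
    already exceed both thresholds), so the +/-1-register rescoring window
    recovers them.
    """
    if threshold is None:
        threshold = default_threshold(mode)
    m = mirna.sequence
    t_id = getattr(transcript, "id", "transcript")
    t_seq = getattr(transcript, "sequence", transcript)
    L = len(m)
    if len(t_seq) < L:
        raise ValueError("transcript shorter than miRNA")
    t_codes = _encode(t_seq)
    pen = _ungapped_profile(m, t_codes)
    est = _window_min_costs(pen, mode)

    cand = np.flatnonzero(est <= threshold + _SCAN_MARGIN)
    scored: list[tuple[int, TargetHit, float]] = []
    for p in cand:
        lo = max(0, p - 1)
        hi = min(len(t_seq), p + L + 1)
        site = t_seq[lo:hi]
        sc = score_duplex(m, site, mode)
        if not _passes(sc.expectation, mode, threshold):
            continue
        if not sc.pair_map:
            continue
        s_local = min(sc.pair_map.values())
        e_local = max(sc.pair_map.values())
        # re-base the pairing map on the reported site interval so that
        # site_start + pair_map[pos] - 1 is a transcript coordinate
        sc = replace(
            sc, pair_map={pos: p - s_local + 1 for pos, p in sc.pair_map.items()}
        )
        hit = TargetHit(mirna.id, t_id, lo + s_local, lo + e_local, sc)
        scored.append((int(p), hit, sc.expectation))

    # left-to-right non-overlapping local optima
    hits: list[TargetHit] = []
    i = 0
    while i < len(scored):
        j = i
        best = i
        while j + 1 < len(scored) and scored[j + 1][0] <= scored[best][0] + L - 1:
            j += 1
            if scored[j][2] < scored[best][2] - 1e-12:
                best = j
        hits.append(scored[best][1])
        i = j + 1
    # de-duplicate identical sites found from adjacent starts
    uniq: dict[tuple, TargetHit] = {}
    for h in hits:
        uniq.setdefault((h.site_start, h.site_end), h)
    return [classify_and_annotate(h) for h in uniq.values()]


# ---------------------------------------------------------------------------
# inhibition type and cleavage site


def classify_inhibition(hit: TargetHit, central_gu_is_mismatch: bool = False) -> str:
    """translation iff miRNA position 10 or 11 is mismatched or gapped."""
    bad = {"mismatch", "gap"}
    if central_gu_is_mismatch:
        bad.add("gu")
    states = hit.score.per_position
    return "translation" if (states[9] in bad or states[10] in bad) else "cleavage"


def predict_cleavage_site(hit: TargetHit) -> int:
    """Transcript position paired with miRNA nt 10 (cut before it, 5' side).

    Only defined for cleavage-type hits; the cut is annotated between the
    returned coordinate and the previous transcript position.
    """
    inh = hit.inhibition or classify_inhibition(hit)
    if inh != "cleavage":
        raise ValueError("cleavage site undefined for a translation-type hit")
    site_pos = hit.score.pair_map.get(10)
    if site_pos is None:  # position 10 faces a target bulge; use neighbour
        site_pos = hit.score.pair_map.get(11)
        if site_pos is None:
            raise ValueError("no pairing information around miRNA position 10")
        site_pos += 1
    return hit.site_start + site_pos - 1


def classify_and_annotate(hit: TargetHit, central_gu_is_mismatch: bool = False) -> TargetHit:
    inh = classify_inhibition(hit, central_gu_is_mismatch)
    hit = replace(hit, inhibition=inh)
    if inh == "cleavage":
        hit = replace(hit, cleavage_position=predict_cleavage_site(hit))
    return hit


# ---------------------------------------------------------------------------
# consensus of the two modes


def intersect_modes(
    hits_psr: Iterable[TargetHit], hits_tf: Iterable[TargetHit]
) -> list[ConsensusHit]:
    """Keep (miRNA, transcript) pairs found by both modes at overlapping sites."""
    by_pair: dict[tuple[str, str], list[TargetHit]] = {}
    for h in hits_tf:
        by_pair.setdefault((h.mirna_id, h.transcript_id), []).append(h)
    out: list[ConsensusHit] = []
    for h in hits_psr:
        partners = by_pair.get((h.mirna_id, h.transcript_id), [])
        mate = next(
            (p for p in partners if min(h.site_end, p.site_end) >= max(h.site_start, p.site_start)),
            None,
        )
        if mate is None:
            continue
        out.append(
            ConsensusHit(
                h.mirna_id,
                h.transcript_id,
                h.site_start,
                h.site_end,
                h.score.expectation,
                mate.score.expectation,
                h.inhibition or classify_inhibition(h),
                h.cleavage_position,
            )
        )
    return out


# ---------------------------------------------------------------------------
# optional accessibility (UPE) post-filter


def compute_upe(
    transcript_seq: str,
    site_start: int,
    site_end: int,
    upstream: int = 17,
    downstream: int = 13,
) -> float:
    """Energy (kcal/mol) to open the target site: MFE(site forced unpaired) -
    MFE(unconstrained) over the site plus 17-nt upstream / 13-nt downstream
    flanks.  Used as an optional post-filter (default threshold 25)."""
    import RNA

    lo = max(1, site_start - upstream)
    hi = min(len(transcript_seq), site_end + downstream)
    region = transcript_seq[lo - 1 : hi]
    fc = RNA.fold_compound(region)
    _, mfe_free = fc.mfe()
    fc2 = RNA.fold_compound(region)
    for k in range(site_start - lo + 1, site_end - lo + 2):
        fc2.hc_add_up(k)
    _, mfe_open = fc2.mfe()
    return max(0.0, mfe_open - mfe_free)


def filter_by_upe(hits: list[TargetHit], transcripts: dict[str, str], upe_max: float = 25.0) -> list[TargetHit]:
    kept = []
    for h in hits:
        upe = compute_upe(transcripts[h.transcript_id], h.site_start, h.site_end)
        if upe <= upe_max:
            kept.append(replace(h, upe=upe))
    return kept
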