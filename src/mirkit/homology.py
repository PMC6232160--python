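"""Local similarity search between reference precursors and transcripts.

Candidates are detected by optimal local alignment under BLASTN-like scoring
(match +2, mismatch -3, gap open 5, gap extend 2; a gap of length k costs
open + k*extend) with Karlin-Altschul E-values (default K=0.41,
lambda=0.625) and an E-value cutoff of 10.  Both strands are searched.
Exact affine-gap local alignment is delegated to Bio.Align.PairwiseAligner.

Mismatches "over the whole alignment length" (substitutions plus end
overhangs) are the unit-cost edit distance, computed with edlib.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import edlib
from Bio import Align

from .seqio import reverse_complement

BLASTN_SCORING = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}
KARLIN_K = 0.41
KARLIN_LAMBDA = 0.625


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment, 1-based closed intervals on query and subject."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # '+' or '-'
    score: float
    identities: int
    mismatches: int
    gaps: int
    evalue: float = math.inf

    @property
    def alignment_length(self) -> int:
        return self.identities + self.mismatches + self.gaps


def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    # gap of length k costs open + k*extend
    aligner.open_gap_score = -(scoring["gap_open"] + scoring["gap_extend"])
    aligner.extend_gap_score = -scoring["gap_extend"]
    return aligner


def _hit_from_alignment(aln, query: str, subject: str, qid: str, sid: str, strand: str,
                        subject_len: int) -> AlignmentHit:
    qblocks, sblocks = aln.aligned
    ident = mism = gaps = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                ident += 1
            else:
                mism += 1
    for k in range(1, len(qblocks)):
        gaps += (qblocks[k][0] - qblocks[k - 1][1]) + (sblocks[k][0] - sblocks[k - 1][1])
    q_start, q_end = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
    s_start, s_end = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
    if strand == "-":
        # map coordinates on the reverse-complemented subject back to + strand
        s_start, s_end = subject_len - s_end + 1, subject_len - s_start + 1
    return AlignmentHit(
        qid, sid, q_start, q_end, s_start, s_end, strand,
        float(aln.score), ident, mism, gaps,
    )


def local_align(
    query: str,
    subject: str,
    scoring: dict = BLASTN_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
    both_strands: bool = True,
) -> Optional[AlignmentHit]:
    """Best local alignment of query vs subject (both strands).

    Returns None when nothing scores above zero.  Ties between strands go to
    the + strand, then to the lowest subject start.
    """
    if not query or not subject:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scoring)
    strands = ["+", "-"] if both_strands else ["+"]
    # score-only pass first (cheap); traceback only on the winning strand,
    # preferring + on score ties
    best_strand, best_score = None, 0.0
    for strand in strands:
        sub = subject if strand == "+" else reverse_complement(subject)
        s = aligner.score(query, sub)
        if s > best_score + 1e-9:
            best_strand, best_score = strand, s
    if best_strand is None:
        return None
    sub = subject if best_strand == "+" else reverse_complement(subject)
    alns = aligner.align(query, sub)
    return _hit_from_alignment(
        alns[0], query, sub, query_id, subject_id, best_strand, len(subject)
    )


def evalue_of(score: float, query_length: int, database_length: int,
              K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if query_length <= 0 or database_length <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * query_length * database_length * math.exp(-lam * score)


def with_evalue(hit: AlignmentHit, query_length: int, database_length: int,
                K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> AlignmentHit:
    return replace(hit, evalue=evalue_of(hit.score, query_length, database_length, K, lam))


def _interval_overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if hi < lo:
        return 0.0
    inter = hi - lo + 1
    return inter / min(a[1] - a[0] + 1, b[1] - b[0] + 1)


def best_hits(
    hits: list[AlignmentHit],
    evalue_cutoff: float = 10.0,
    redundancy_overlap: float = 0.8,
) -> dict[str, AlignmentHit]:
    """Per query, keep the single best hit under the E-value cutoff.

    Best = lowest E-value; ties broken by highest score, then lexicographic
    subject id.  After selection, hits of different queries landing on the
    same subject region (interval overlap >= ``redundancy_overlap``) are
    collapsed to the best one, eliminating redundant candidate regions.
    """
    kept: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = kept.get(hit.query_id)
        if cur is None or (hit.evalue, -hit.score, hit.subject_id) < (
            cur.evalue, -cur.score, cur.subject_id
        ):
            kept[hit.query_id] = hit

    # collapse redundant subject regions across queries
    order = sorted(kept.values(), key=lambda h: (h.evalue, -h.score, h.query_id))
    winners: list[AlignmentHit] = []
    result: dict[str, AlignmentHit] = {}
    for hit in order:
        redundant = any(
            w.subject_id == hit.subject_id
            and _interval_overlap_frac(
                (w.subject_start, w.subject_end), (hit.subject_start, hit.subject_end)
            )
            >= redundancy_overlap
            for w in winners
        )
        if not redundant:
            winners.append(hit)
            result[hit.query_id] = hit
    return result


def whole_length_mismatches(a: str, b: str) -> int:
    """Mismatches of the global alignment of a and b.

    Substitutions and end overhangs each count one; this is the unit-cost
    edit distance between the two sequences.
    """
    if not a and not b:
        return 0
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, mode="NW")["editDistance"]


def blastn_align(
    queries,
    subjects,
    evalue_cutoff: float = 10.0,
    word_size: int = 11,
    executable: str = "blastn",
) -> list[AlignmentHit]:
    """Optional adapter: run an external blastn behind the same contract.

    Writes queries and subjects to temporary FASTA files, runs
    ``blastn -subject`` with tabular output and maps rows to
    :class:`AlignmentHit` (E-values are blastn's own).  Raises
    FileNotFoundError when the executable is absent.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    def as_dna(records):
        out = []
        for r in records:
            seq = getattr(r, "sequence", r).replace("U", "T")
            out.append((getattr(r, "id", f"seq{len(out)}"), seq))
        return out

    with tempfile.TemporaryDirectory() as td:
        qf, sf = Path(td) / "q.fasta", Path(td) / "s.fasta"
        for path, records in ((qf, as_dna(queries)), (sf, as_dna(subjects))):
            with open(path, "w") as fh:
                for rid, seq in records:
                    fh.write(f">{rid}\n{seq}\n")
        out = subprocess.run(
            [
                executable, "-query", str(qf), "-subject", str(sf),
                "-task", "blastn", "-word_size", str(word_size),
                "-evalue", str(evalue_cutoff), "-strand", "both",
                "-outfmt", "6 qseqid sseqid pident length mismatch gapopen "
                           "qstart qend sstart send evalue score",
            ],
            capture_output=True, text=True, check=True,
        )
    hits = []
    for line in out.stdout.splitlines():
        (qid, sid, pident, length, mism, gapopen, qs, qe, ss, se, ev, sc) = (
            line.split("\t")
        )
        s_start, s_end = int(ss), int(se)
        strand = "+" if s_start <= s_end else "-"
        if strand == "-":
            s_start, s_end = s_end, s_start
        length, mism = int(length), int(mism)
        hits.append(
            AlignmentHit(
                qid, sid, int(qs), int(qe), s_start, s_end, strand,
                float(sc), length - mism - int(gapopen), mism, int(gapopen),
                evalue=float(ev),
            )
        )
    return hits


def hits_to_rows(hits: list[AlignmentHit]) -> list[dict]:
    """Tabular-BLAST shaped rows (qseqid .. bitscore) for TSV export."""
    rows = []
    for h in hits:
        length = h.alignment_length
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(100.0 * h.identities / length, 2) if length else 0.0,
                "length": length,
                "mismatch": h.mismatches,
                "gapopen": h.gaps,
                "qstart": h.query_start,
                "qend": h.query_end,
                "sstart": h.subject_start if h.strand == "+" else h.subject_end,
                "send": h.subject_end if h.strand == "+" else h.subject_start,
                "evalue": h.evalue,
                "bitscore": h.score,
            }
        )
    return rows
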