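"""Sequence I/O and the core record types shared by all pipeline stages.

Sequences are held internally in the RNA alphabet ({A, C, G, U}): every
downstream quantity (A+U content, G:U wobble pairing, folding) lives in the
RNA domain, so DNA input is converted once, on read.  IUPAC ambiguity codes
are preserved by the reader; candidates containing them are rejected later by
the hairpin filters with an explicit reason, because mismatch counting is
undefined for ambiguous bases.

Coordinates everywhere in this package are 1-based, closed intervals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

IUPAC_NT = set("ACGUTRYSWKMBDHVN")
UNAMBIGUOUS_RNA = set("ACGU")

TISSUES = ("bud", "culm", "leaf", "root")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, duplicate id, empty seq)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, alphabet: str = "auto") -> tuple[str, str]:
    """Uppercase and convert to RNA; return (sequence, alphabet_origin).

    ``alphabet`` is one of ``dna``, ``rna``, ``auto``.  In auto mode the
    origin is called DNA if the raw sequence contains T and no U.
    Idempotent: normalising an already-normalised sequence is a no-op.
    """
    s = raw.upper().replace(" ", "")
    bad = set(s) - IUPAC_NT
    if bad:
        raise FastaParseError(f"non-nucleotide characters {sorted(bad)} in sequence")
    if alphabet == "auto":
        origin = "dna" if ("T" in s and "U" not in s) else "rna"
    else:
        origin = alphabet
    return s.replace("T", "U"), origin


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA entry, normalised to the RNA alphabet."""

    id: str
    sequence: str
    description: str = ""
    alphabet_origin: Literal["dna", "rna"] = "rna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_ambiguous(self) -> bool:
        return bool(set(self.sequence) - UNAMBIGUOUS_RNA)


@dataclass(frozen=True)
class Transcript:
    """A transcriptome entry carrying the tissue its assembly came from."""

    record: SequenceRecord
    tissue: str = "unknown"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES + ("unknown",):
            raise ValueError(f"unknown tissue label {self.tissue!r}")

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence


@dataclass
class ReferenceMiRNA:
    """A reference precursor with its annotated mature sequence(s).

    ``family`` is parsed from the miRBase-style name (e.g. ``osa-MIR169a``
    -> ``MIR169``); matures whose sequence is not found inside the precursor
    are kept but flagged ``detached``.
    """

    name: str
    family: str
    species_code: str
    precursor: SequenceRecord
    matures: list[SequenceRecord] = field(default_factory=list)
    detached: set[str] = field(default_factory=set)
    homolog_of: str | None = None  # closest locus in the prediction reference species


_NAME_RE = re.compile(
    r"^(?P<species>[a-zA-Z]{3})-(?P<kind>MIR|miR)(?P<fam>\d+)"
    r"(?P<variant>[a-z]*)(?P<rest>.*)$"
)


def parse_mirna_name(name: str) -> dict:
    """Split a miRBase-style name into species code, family, variant, arm.

    ``osa-miR169a-5p`` -> species ``osa``, family ``MIR169``, variant ``a``,
    arm ``5p``.  Raises ValueError for names not following the convention.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse miRNA name {name!r}")
    rest = m.group("rest")
    arm = ""
    if rest.endswith("-5p") or rest.endswith("-3p"):
        arm = rest[-2:]
    return {
        "species_code": m.group("species").lower(),
        "family": "MIR" + m.group("fam"),
        "variant": m.group("variant"),
        "arm": arm,
    }


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Line wrapping is irrelevant; sequences are uppercased and T->U converted
    (``alphabet='rna'`` or auto-detected).  Errors: a file whose first
    non-blank line is not a header raises :class:`FastaParseError` naming the
    line number; so do duplicate ids and empty sequences.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        seq, origin = normalize_sequence(str(rec.seq), alphabet)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, seq, desc, origin))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> Path:
    """Write records as FASTA at the given wrap width (input order kept)."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    if wrap <= 0:
        raise ValueError(f"wrap width must be positive, got {wrap}")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")
    return path


def parse_reference_set(
    precursor_fasta: str | Path, mature_fasta: str | Path
) -> list[ReferenceMiRNA]:
    """Pair precursor and mature FASTA files into :class:`ReferenceMiRNA`.

    Matures map to precursors by the miR/MIR prefix convention, tolerating
    -5p/-3p suffixes.  A mature with no matching precursor triggers a warning
    and is attached to nothing; a mature whose sequence is not a substring of
    its precursor is flagged detached (not fatal).
    """
    precursors = read_fasta(precursor_fasta, alphabet="auto")
    matures = read_fasta(mature_fasta, alphabet="auto")

    refs: dict[str, ReferenceMiRNA] = {}
    for prec in precursors:
        info = parse_mirna_name(prec.id)
        refs[prec.id.lower().replace("mir", "mir")] = ReferenceMiRNA(
            name=prec.id,
            family=info["family"],
            species_code=info["species_code"],
            precursor=prec,
        )
    # index by case-insensitive stem (osa-mir169a) for mature lookup
    by_stem = {r.name.lower(): r for r in refs.values()}

    for mat in matures:
        stem = re.sub(r"-(5p|3p)$", "", mat.id).lower()
        ref = by_stem.get(stem)
        if ref is None:
            warnings.warn(f"mature {mat.id!r} has no matching precursor; skipped")
            continue
        ref.matures.append(mat)
        if mat.sequence not in ref.precursor.sequence:
            ref.detached.add(mat.id)
    return list(by_stem.values())


def write_tsv(rows: list[dict], path: str | Path) -> Path:
    """Write a list of dict rows as a UTF-8 TSV with '.' for missing values."""
    import pandas as pd

    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return Path(path)
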