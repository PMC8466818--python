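"""Sequence substrate: records, FASTA I/O, ORF scanning, cds classification, translation.

Every downstream stage (variant calling, clade typing, in-silico PCR, phylogenetics)
operates on :class:`SequenceRecord` objects produced here.  Coordinates are 1-based
and end-inclusive throughout the package, counted from the A of the start codon for
cds-relative positions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("cansynth")

#: IUPAC nucleotide one-letter codes (uppercase).  '-' is tolerated in aligned input.
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN-")

#: Map of IUPAC code -> set of unambiguous bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class Role(str, Enum):
    """What a sequence is used as in a run."""

    reference = "reference"
    query = "query"
    template = "template"
    amplicon = "amplicon"


class FastaFormatError(ValueError):
    """Raised on empty or malformed FASTA input."""


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence.

    The sequence is case-normalized to upper on construction and restricted to
    IUPAC nucleotide codes (plus ``-`` so pre-aligned input can be carried).
    """

    id: str
    seq: str
    description: str = ""
    role: Role = Role.query

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if isinstance(self.role, str) and not isinstance(self.role, Role):
            self.role = Role(self.role)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            seq=str(Seq(self.seq).reverse_complement()),
            description=self.description,
            role=self.role,
        )


class CdsStatusKind(str, Enum):
    complete = "complete"
    pseudogene = "pseudogene"
    fragment = "fragment"


@dataclass
class CdsStatus:
    """Classification of a putative coding sequence.

    ``complete``   — starts with ATG, ends with an in-frame stop, length divisible
                     by 3 and no internal stop codon.
    ``pseudogene`` — reading frame interrupted: internal stop and/or a
                     frameshift-length (start and stop present, length % 3 != 0).
    ``fragment``   — lacks the start and/or the terminal stop codon.
    """

    status: CdsStatusKind
    length_nt: int
    reason: str = ""


@dataclass
class Protein:
    """A translated amino-acid sequence (one-letter code, no terminal stop)."""

    id: str
    aa: str

    def __len__(self) -> int:
        return len(self.aa)


class InternalStopError(ValueError):
    """Translation hit a stop codon before the final codon."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop at codon {codon_index}")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, role: Role = Role.query) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Order is preserved and sequences are upper-cased.  Duplicate ids are accepted
    with a logged warning.  An empty file or a file whose first non-blank line is
    not a header raises :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno} is not a FASTA header: {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not str(rec.seq):
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            log.warning("duplicate FASTA id %r in %s (accepted)", rec.id, path)
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description, role=role)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapped at ``width`` columns (default 70)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}" if not rec.description.startswith(rec.id)
                else rec.description
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# cds classification
# ---------------------------------------------------------------------------

def validate_cds(rec: SequenceRecord) -> CdsStatus:
    """Classify a sequence as complete cds, pseudogene or fragment.

    Ambiguity codes are tolerated in the body but not inside the first or last
    codon (a ``ValueError`` is raised there, since start/stop identity cannot be
    established).
    """
    s = rec.seq
    n = len(s)
    if n < 6:
        raise ValueError(f"{rec.id}: sequence shorter than 6 nt cannot be a cds")
    if set(s[:3]) - set("ACGT") or set(s[-3:]) - set("ACGT"):
        raise ValueError(f"{rec.id}: ambiguity codes in the start or stop codon")

    has_start = s.startswith(START_CODON)
    has_stop = s[-3:] in STOP_CODONS
    if not has_start or not has_stop:
        missing = []
        if not has_start:
            missing.append("start codon")
        if not has_stop:
            missing.append("terminal stop codon")
        return CdsStatus(CdsStatusKind.fragment, n, "lacks " + " and ".join(missing))
    if n % 3 != 0:
        return CdsStatus(
            CdsStatusKind.pseudogene, n, f"frameshift-length ({n} nt not divisible by 3)"
        )
    n_codons = n // 3
    for ci in range(1, n_codons - 1):  # skip start (0) and terminal stop (n_codons-1)
        if s[3 * ci : 3 * ci + 3] in STOP_CODONS:
            return CdsStatus(
                CdsStatusKind.pseudogene, n, f"internal stop at codon {ci + 1}"
            )
    return CdsStatus(CdsStatusKind.complete, n, "")


def cds_status_table(records: Sequence[SequenceRecord]):
    """Status report as a DataFrame: id, status, length_nt, reason (TSV-ready)."""
    import pandas as pd

    rows = []
    for rec in records:
        st = validate_cds(rec)
        rows.append(
            {"id": rec.id, "status": st.status.value, "length_nt": st.length_nt,
             "reason": st.reason}
        )
    return pd.DataFrame(rows, columns=["id", "status", "length_nt", "reason"])


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def find_orfs(rec: SequenceRecord, min_len_nt: int) -> list[tuple[int, int, str]]:
    """Scan both strands for complete ORFs (ATG .. in-frame stop).

    Per reading frame, the maximal ORF for each stop codon is reported: the one
    starting at the first ATG after the previous in-frame stop.  Coordinates are
    1-based, end-inclusive, on the *plus* strand of the given template; minus-strand
    ORFs are reported with mirrored coordinates and strand ``'-'``.  Result sorted
    by start, then strand ('+' before '-').
    """
    if min_len_nt < 6 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be >= 6 and divisible by 3")
    n = len(rec.seq)
    out: list[tuple[int, int, str]] = []
    for strand, s in (("+", rec.seq), ("-", str(Seq(rec.seq).reverse_complement()))):
        for frame in range(3):
            pending_atg: int | None = None  # 0-based position of first ATG since last stop
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if pending_atg is not None:
                        start0, end0 = pending_atg, i + 2
                        if end0 - start0 + 1 >= min_len_nt:
                            if strand == "+":
                                out.append((start0 + 1, end0 + 1, "+"))
                            else:
                                out.append((n - end0, n - start0, "-"))
                    pending_atg = None
                elif codon == START_CODON and pending_atg is None:
                    pending_atg = i
    out.sort(key=lambda t: (t[0], t[2]))
    return out


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate(cds: str | SequenceRecord) -> Protein:
    """Translate a complete cds under the standard genetic code.

    The terminal stop is dropped.  Ambiguous codons translate to ``X`` with a
    logged warning.  An internal stop raises :class:`InternalStopError` carrying
    the codon index.
    """
    if isinstance(cds, SequenceRecord):
        rec_id, s = cds.id, cds.seq
    else:
        rec_id, s = "cds", cds.upper()
    if len(s) % 3 != 0:
        raise ValueError(f"{rec_id}: cds length {len(s)} not divisible by 3")
    aa = str(Seq(s).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    star = aa.find("*")
    if star != -1:
        raise InternalStopError(star + 1)
    if "X" in aa:
        log.warning("%s: ambiguous codon(s) translated to X at position(s) %s",
                    rec_id, [i + 1 for i, a in enumerate(aa) if a == "X"])
    return Protein(id=rec_id, aa=aa)
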