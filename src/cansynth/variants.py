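"""SNP calling against a reference cds, percent identity, codon mapping and
substitution-effect annotation.

The cannabinoid synthase paralogs are co-linear single-exon genes, so equal-length
sequences are compared positionally; a global alignment path handles unequal
lengths.  Identities are rounded half-up to two decimals, the precision at which
they are conventionally reported (99.94, 99.82, ...).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .seq import Protein, SequenceRecord

log = logging.getLogger("cansynth")


class Effect(str, Enum):
    synonymous = "synonymous"
    missense = "missense"
    nonsense = "nonsense"


@dataclass
class Snp:
    """A single-nucleotide substitution relative to a reference cds.

    ``pos_nt`` is 1-based from the A of ATG; ``codon_index`` follows
    ``floor((pos_nt - 1) / 3) + 1``.
    """

    pos_nt: int
    ref_allele: str
    alt_allele: str
    codon_index: int
    effect: Effect
    aa_from: str | None = None
    aa_to: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP at {self.pos_nt}: ref and alt alleles are equal")


@dataclass
class SnpTable:
    query_id: str
    reference_id: str
    snps: list[Snp]
    aligned_length_nt: int
    identity_pct: float
    gap_columns: int = 0  # indel columns, excluded from the SNP list


@dataclass
class CriticalResidueReport:
    residues_checked: list[tuple[int, str]]
    all_intact: bool
    deviations: list[tuple[int, str, str]] = field(default_factory=list)


#: Residues required for synthase activity: Arg110..His114 and Cys176.
#: Positions 111-113 are checked against whatever the supplied reference protein
#: carries; 110, 114 and 176 have fixed expectations.
CriticalResidueSet = list


def _round2(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Pairwise percent identity, rounded half-up to 2 decimals; symmetric.

    Equal-length sequences are compared position by position.  Unequal lengths
    go through a global alignment (match +1, mismatch -1, gap -2, end gaps
    penalized); identity is matches / alignment columns x 100.
    """
    if not a.seq or not b.seq:
        raise ValueError("percent_identity requires non-empty sequences")
    if len(a.seq) == len(b.seq):
        matches = sum(x == y for x, y in zip(a.seq, b.seq))
        return _round2(Decimal(matches * 100) / Decimal(len(a.seq)))
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    aln = aligner.align(a.seq, b.seq)[0]
    idx = aln.indices  # 2 x columns; -1 marks a gap
    cols = idx.shape[1]
    matches = sum(
        1 for c in range(cols)
        if idx[0, c] >= 0 and idx[1, c] >= 0 and a.seq[idx[0, c]] == b.seq[idx[1, c]]
    )
    return _round2(Decimal(matches * 100) / Decimal(cols))


def codon_index(pos_nt: int) -> int:
    """Codon (residue) number containing nucleotide ``pos_nt`` (both 1-based)."""
    if pos_nt < 1:
        raise ValueError(f"pos_nt must be >= 1, got {pos_nt}")
    return (pos_nt - 1) // 3 + 1


def classify_substitution(
    snp_pos: int, alt: str, reference_cds: str
) -> tuple[Effect, str | None, str | None]:
    """Effect of substituting ``alt`` at ``snp_pos`` of a reference cds.

    The codon containing the position is mutated and both codons translated;
    the effect is synonymous / missense / nonsense accordingly.  For a nonsense
    change ``aa_to`` is ``'*'``.
    """
    reference_cds = reference_cds.upper()
    alt = alt.upper()
    if not (1 <= snp_pos <= len(reference_cds)):
        raise ValueError(f"snp_pos {snp_pos} outside cds of length {len(reference_cds)}")
    ref_base = reference_cds[snp_pos - 1]
    if alt == ref_base:
        raise ValueError(f"alt allele equals reference base {ref_base} at {snp_pos}")
    ci = codon_index(snp_pos)
    codon_start = 3 * (ci - 1)
    ref_codon = reference_cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"position {snp_pos} falls in an incomplete terminal codon")
    if set(ref_codon) - set("ACGT"):
        raise ValueError(f"reference codon {ci} ({ref_codon}) is ambiguous")
    offset = snp_pos - 1 - codon_start
    alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
    aa_from = str(Seq(ref_codon).translate(table=1))
    aa_to = str(Seq(alt_codon).translate(table=1))
    if aa_to == "*":
        return Effect.nonsense, aa_from, "*"
    if aa_from == aa_to:
        return Effect.synonymous, aa_from, aa_to
    return Effect.missense, aa_from, aa_to


def call_snps(
    query: SequenceRecord, reference: SequenceRecord, align: bool = False
) -> SnpTable:
    """Call substitutions of ``query`` against ``reference``.

    Equal-length inputs are compared positionally (the default for the co-linear
    synthase cds).  Unequal lengths require ``align=True``; indel columns are
    counted in ``gap_columns`` and excluded from the SNP list, and positions are
    reported in reference coordinates.
    """
    snps: list[Snp] = []
    if len(query.seq) == len(reference.seq):
        length = len(reference.seq)
        gap_cols = 0
        for i, (r, q) in enumerate(zip(reference.seq, query.seq), start=1):
            if r == "-" or q == "-":
                gap_cols += 1
                continue
            if r != q:
                eff, aa_f, aa_t = classify_substitution(i, q, reference.seq)
                snps.append(Snp(i, r, q, codon_index(i), eff, aa_f, aa_t))
        ident = _round2(Decimal((length - len(snps) - gap_cols) * 100) / Decimal(length))
        return SnpTable(query.id, reference.id, snps, length, ident, gap_cols)
    if not align:
        raise ValueError(
            f"length mismatch ({len(query.seq)} vs {len(reference.seq)}); "
            "pass align=True to align first"
        )
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    aln = aligner.align(reference.seq, query.seq)[0]
    idx = aln.indices
    cols = idx.shape[1]
    gap_cols = 0
    for c in range(cols):
        ri, qi = idx[0, c], idx[1, c]
        if ri < 0 or qi < 0:
            gap_cols += 1
            continue
        r, q = reference.seq[ri], query.seq[qi]
        if r != q:
            eff, aa_f, aa_t = classify_substitution(ri + 1, q, reference.seq)
            snps.append(Snp(ri + 1, r, q, codon_index(ri + 1), eff, aa_f, aa_t))
    ident = _round2(Decimal((cols - len(snps) - gap_cols) * 100) / Decimal(cols))
    return SnpTable(query.id, reference.id, snps, cols, ident, gap_cols)


def default_critical_residues(reference_protein: Protein) -> list[tuple[int, str]]:
    """The activity-critical residue set: positions 110-114 and 176.

    110 must be R, 114 H and 176 C; 111-113 are taken from the supplied
    reference protein.  Met of the start codon is residue 1.
    """
    if len(reference_protein.aa) < 176:
        raise ValueError("reference protein shorter than residue 176")
    aa = reference_protein.aa
    if aa[109] != "R" or aa[113] != "H" or aa[175] != "C":
        log.warning(
            "reference protein deviates at canonical critical residues "
            "(110=%s, 114=%s, 176=%s)", aa[109], aa[113], aa[175]
        )
    out = [(110, "R")]
    out += [(p, aa[p - 1]) for p in (111, 112, 113)]
    out += [(114, "H"), (176, "C")]
    return out


def check_critical_residues(
    p: Protein, profile: Sequence[tuple[int, str]]
) -> CriticalResidueReport:
    """Check a protein against a list of (position, expected amino acid)."""
    max_pos = max(pos for pos, _ in profile)
    if len(p.aa) < max_pos:
        raise ValueError(f"{p.id}: protein length {len(p.aa)} < checked position {max_pos}")
    deviations = [
        (pos, expected, p.aa[pos - 1])
        for pos, expected in profile
        if p.aa[pos - 1] != expected
    ]
    return CriticalResidueReport(list(profile), not deviations, deviations)


def snp_table_to_frame(table: SnpTable) -> pd.DataFrame:
    """SNP table as a DataFrame with the TSV report columns."""
    rows = [
        {
            "query_id": table.query_id, "reference_id": table.reference_id,
            "pos_nt": s.pos_nt, "ref": s.ref_allele, "alt": s.alt_allele,
            "codon": s.codon_index, "effect": s.effect.value,
            "aa_from": s.aa_from, "aa_to": s.aa_to,
        }
        for s in table.snps
    ]
    return pd.DataFrame(
        rows, columns=["query_id", "reference_id", "pos_nt", "ref", "alt",
                       "codon", "effect", "aa_from", "aa_to"]
    )


def identity_matrix(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over a set of records."""
    ids = [r.id for r in records]
    df = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(records):
        for j in range(i + 1, len(records)):
            v = percent_identity(a, records[j])
            df.iloc[i, j] = v
            df.iloc[j, i] = v
    return df
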