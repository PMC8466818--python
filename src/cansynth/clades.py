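"""Clade-diagnostic SNP discovery and paralog classification.

THCAS, CBDAS and CBCAS coding sequences are near-identical (>= ~84% pairwise,
95-96% between CBCAS and THCAS), so a handful of clade-fixed positions — e.g.
cds positions 13, 18 and 1628 separating CBCAS from THCAS — carry the entire
discriminating signal.  This module finds such positions among labeled sets and
assigns unknown complete cds to a gene class.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .seq import SequenceRecord
from .variants import percent_identity

log = logging.getLogger("cansynth")


@dataclass
class CladeProfile:
    """A named gene class: reference cds + diagnostic (pos, allele) pairs."""

    name: str
    reference: SequenceRecord
    diagnostic: list[tuple[int, str]]
    critical_residues: list[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.diagnostic]
        if len(set(positions)) != len(positions):
            raise ValueError(f"profile {self.name}: duplicate diagnostic positions")
        for p, allele in self.diagnostic:
            if not (1 <= p <= len(self.reference.seq)):
                raise ValueError(
                    f"profile {self.name}: diagnostic position {p} outside reference"
                )
            if allele not in "ACGT":
                raise ValueError(f"profile {self.name}: diagnostic allele must be ACGT")


@dataclass
class CladeCall:
    query_id: str
    assigned: str  # clade name or "unknown"
    identity_to_each: dict[str, float] = field(default_factory=dict)
    diagnostic_matches: dict[str, float] = field(default_factory=dict)
    rationale: str = ""


def discover_diagnostic_positions(
    clade_a: Sequence[SequenceRecord],
    clade_b: Sequence[SequenceRecord],
    minor_allele_tolerance: float = 0.0,
) -> list[tuple[int, str, str]]:
    """Positions fixed within each clade and different between them.

    Returns (pos, allele_a, allele_b) sorted by position.  With the default
    tolerance of 0 a position must be strictly fixed (one allele) within each
    clade; ``minor_allele_tolerance`` relaxes fixation to a maximum minor-allele
    frequency.  Sequences must be equal-length co-linear cds.
    """
    if len(clade_a) < 2 or len(clade_b) < 2:
        raise ValueError("need >= 2 sequences per clade")
    lengths = {len(r.seq) for r in list(clade_a) + list(clade_b)}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have unequal lengths {sorted(lengths)}; align them first"
        )
    (length,) = lengths
    out: list[tuple[int, str, str]] = []
    for i in range(length):
        allele_a = _fixed_allele([r.seq[i] for r in clade_a], minor_allele_tolerance)
        if allele_a is None:
            continue
        allele_b = _fixed_allele([r.seq[i] for r in clade_b], minor_allele_tolerance)
        if allele_b is None or allele_a == allele_b:
            continue
        out.append((i + 1, allele_a, allele_b))
    return out


def _fixed_allele(column: list[str], tolerance: float) -> str | None:
    """Majority allele if the column is fixed up to ``tolerance``; else None.

    Ambiguity codes never count as a fixed allele.
    """
    counts: dict[str, int] = {}
    for base in column:
        counts[base] = counts.get(base, 0) + 1
    major = max(counts, key=lambda b: (counts[b], b))
    if major not in "ACGT":
        return None
    minor_freq = 1.0 - counts[major] / len(column)
    return major if minor_freq <= tolerance else None


def classify_sequence(
    query: SequenceRecord,
    profiles: Sequence[CladeProfile],
    identity_threshold: float = 97.0,
) -> CladeCall:
    """Assign a complete cds to a clade, or "unknown".

    A clade qualifies iff *all* its diagnostic alleles match exactly (ambiguity
    codes in the query count as non-matching) and identity to its reference is
    at or above ``identity_threshold``.  Ties are broken by highest identity,
    then by profile registration order (logged).
    """
    if not profiles:
        raise ValueError("no clade profiles registered")
    identities: dict[str, float] = {}
    matches: dict[str, float] = {}
    qualified: list[tuple[int, CladeProfile]] = []
    for order, prof in enumerate(profiles):
        ident = percent_identity(query, prof.reference)
        identities[prof.name] = ident
        n_match = sum(
            1 for pos, allele in prof.diagnostic
            if pos <= len(query.seq) and query.seq[pos - 1] == allele
        )
        frac = n_match / len(prof.diagnostic) if prof.diagnostic else 1.0
        matches[prof.name] = frac
        if frac == 1.0 and ident >= identity_threshold:
            qualified.append((order, prof))
    if not qualified:
        return CladeCall(
            query.id, "unknown", identities, matches,
            "no profile with full diagnostic match and identity >= "
            f"{identity_threshold}",
        )
    qualified.sort(key=lambda t: (-identities[t[1].name], t[0]))
    if len(qualified) > 1:
        log.info(
            "%s: %d profiles qualified; tie broken by identity then order -> %s",
            query.id, len(qualified), qualified[0][1].name,
        )
    winner = qualified[0][1]
    return CladeCall(
        query.id, winner.name, identities, matches,
        f"all {len(winner.diagnostic)} diagnostic alleles match; "
        f"identity {identities[winner.name]:.2f}% >= {identity_threshold}%",
    )


def unique_cds_inventory(
    records: Sequence[SequenceRecord],
    genotype_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Deduplicate records by exact sequence and report cross-genotype recurrence.

    One row per unique sequence: representative id, number of clones, number of
    distinct genotypes, and the sorted genotype list.  ``genotype_labels`` maps
    record id -> genotype name (record id used as its own genotype if absent).
    """
    genotype_labels = genotype_labels or {}
    groups: dict[str, dict] = {}
    order: list[str] = []
    for rec in records:
        if rec.seq not in groups:
            groups[rec.seq] = {"representative": rec.id, "ids": [], "genotypes": []}
            order.append(rec.seq)
        g = groups[rec.seq]
        g["ids"].append(rec.id)
        g["genotypes"].append(genotype_labels.get(rec.id, rec.id))
    rows = []
    for s in order:
        g = groups[s]
        genos = sorted(set(g["genotypes"]))
        rows.append(
            {
                "unique_id": g["representative"],
                "n_clones": len(g["ids"]),
                "n_genotypes": len(genos),
                "genotypes": ",".join(genos),
            }
        )
    return pd.DataFrame(rows, columns=["unique_id", "n_clones", "n_genotypes", "genotypes"])
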