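"""In-silico PCR: primer binding-site search, multiplex product prediction,
B1080/B1192 marker interpretation and primer-specificity validation.

The binding model is the standard dry-lab proxy for empirical specificity:
a primer binds where it has at most ``max_mismatch`` mismatches overall and a
perfect 3'-terminal clamp (default: last 3 bases).  IUPAC ambiguity codes in the
template match any compatible base.  Both knobs are exposed on the CLI.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .seq import IUPAC_SETS, SequenceRecord

log = logging.getLogger("cansynth")


@dataclass
class PrimerPair:
    """A primer pair as listed in a primer table (both given 5'->3')."""

    name: str
    fw: str
    rv: str
    expected_len_bp: int | None = None
    ta_celsius: float | None = None
    conc_um: float | None = None

    def __post_init__(self) -> None:
        self.fw = self.fw.upper()
        self.rv = self.rv.upper()
        for label, p in (("fw", self.fw), ("rv", self.rv)):
            if len(p) < 15:
                raise ValueError(f"{self.name}: {label} primer shorter than 15 nt")
            if set(p) - set(IUPAC_SETS):
                raise ValueError(f"{self.name}: {label} primer has non-IUPAC characters")
        if self.expected_len_bp is not None and self.expected_len_bp <= len(self.fw) + len(self.rv):
            raise ValueError(
                f"{self.name}: expected_len_bp must exceed the combined primer length"
            )


@dataclass
class BindingSite:
    """A primer annealing site in plus-strand coordinates (1-based, inclusive).

    ``strand`` '+' means the primer sequence reads along the plus strand (it
    primes rightward synthesis); '-' means it anneals to the plus strand (its
    reverse complement appears there) and primes leftward.
    """

    strand: str
    start: int
    end: int
    mismatches: int


@dataclass
class AmpliconProduct:
    template_id: str
    start: int
    end: int
    length_bp: int
    fw_mismatches: int
    rv_mismatches: int

    def __post_init__(self) -> None:
        assert self.length_bp == self.end - self.start + 1


class BLocus(str, Enum):
    BD_BD = "BD/BD"
    BT_BT = "BT/BT"
    BT_BD = "BT/BD"
    no_call = "no-call"


class Chemotype(str, Enum):
    I = "I"
    II = "II"
    III_IV_V = "III-IV-V"
    undetermined = "undetermined"


@dataclass
class MarkerCall:
    """B-locus genotype read from multiplex band sizes.

    1192 bp marks a functional THCAS (B_T), 1080/1081 bp a functional CBDAS
    (B_D).  Chemotype I (THCA-predominant) = B_T/B_T, II = B_T/B_D, and B_D/B_D
    covers chemotypes III, IV and V indistinctly.
    """

    genotype_id: str
    bands: frozenset[int]
    b_locus: BLocus
    chemotype_class: Chemotype
    reason: str = ""


@dataclass
class SpecificityReport:
    pair_name: str
    passed: bool
    products_by_template: dict[str, list[AmpliconProduct]] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)
    tm_fw: float | None = None
    tm_rv: float | None = None
    tm_note: str = ""


def _bases_compatible(primer_base: str, template_base: str) -> bool:
    p = IUPAC_SETS.get(primer_base)
    t = IUPAC_SETS.get(template_base)
    if p is None or t is None:  # gaps or unknown never match
        return False
    return bool(p & t)


def find_binding_sites(
    primer: str,
    template: SequenceRecord,
    max_mismatch: int = 2,
    clamp_3prime: int = 3,
) -> list[BindingSite]:
    """All annealing sites of a primer on both strands of a template.

    A site qualifies when total mismatches <= ``max_mismatch`` and the
    ``clamp_3prime`` 3'-terminal primer bases match perfectly.  Sites are
    reported in plus-strand coordinates, sorted by start then strand.
    """
    primer = primer.upper()
    m = len(primer)
    t = template.seq
    n = len(t)
    if m > n:
        raise ValueError("primer longer than template")
    sites: list[BindingSite] = []
    rc = str(Seq(primer).reverse_complement())
    for off in range(n - m + 1):
        window = t[off : off + m]
        # plus strand: primer aligned directly; 3' end is the rightmost base
        mm = sum(not _bases_compatible(p, w) for p, w in zip(primer, window))
        if mm <= max_mismatch:
            clamp_ok = all(
                _bases_compatible(primer[m - 1 - k], window[m - 1 - k])
                for k in range(clamp_3prime)
            )
            if clamp_ok:
                sites.append(BindingSite("+", off + 1, off + m, mm))
        # minus strand: reverse complement of the primer appears in the window;
        # the primer 3' end pairs with the leftmost plus-strand base
        mm = sum(not _bases_compatible(p, w) for p, w in zip(rc, window))
        if mm <= max_mismatch:
            clamp_ok = all(_bases_compatible(rc[k], window[k]) for k in range(clamp_3prime))
            if clamp_ok:
                sites.append(BindingSite("-", off + 1, off + m, mm))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_products(
    pair: PrimerPair,
    templates: Sequence[SequenceRecord],
    max_len_bp: int = 5000,
    max_mismatch: int = 2,
    clamp_3prime: int = 3,
) -> list[AmpliconProduct]:
    """Predict amplicons of a primer pair on a set of templates.

    A product forms between a forward-priming site and a downstream
    reverse-priming site on the opposite strand; length is measured from the
    5' end of one primer footprint to the 5' end of the other, inclusive.
    Both template orientations are handled symmetrically.
    """
    out: list[AmpliconProduct] = []
    for tmpl in templates:
        fw_sites = find_binding_sites(pair.fw, tmpl, max_mismatch, clamp_3prime)
        rv_sites = find_binding_sites(pair.rv, tmpl, max_mismatch, clamp_3prime)
        # fw primes rightward from a '+' site; rv anneals as a '-' site downstream
        for f in (s for s in fw_sites if s.strand == "+"):
            for r in (s for s in rv_sites if s.strand == "-"):
                if r.start >= f.start and r.end >= f.end:
                    length = r.end - f.start + 1
                    if length <= max_len_bp:
                        out.append(
                            AmpliconProduct(tmpl.id, f.start, r.end, length,
                                            f.mismatches, r.mismatches)
                        )
        # the mirrored orientation: rv primes rightward, fw anneals downstream
        for r in (s for s in rv_sites if s.strand == "+"):
            for f in (s for s in fw_sites if s.strand == "-"):
                if f.start >= r.start and f.end >= r.end:
                    length = f.end - r.start + 1
                    if length <= max_len_bp:
                        out.append(
                            AmpliconProduct(tmpl.id, r.start, f.end, length,
                                            f.mismatches, r.mismatches)
                        )
    out.sort(key=lambda p: (p.template_id, p.start, p.end))
    return out


def predict_multiplex(
    primers: Sequence[str],
    templates: Sequence[SequenceRecord],
    max_len_bp: int = 5000,
    max_mismatch: int = 2,
    clamp_3prime: int = 3,
) -> list[AmpliconProduct]:
    """Products of every primer combination of a multiplex (e.g. three-primer
    marker systems): any '+' site of one primer paired with a downstream '-'
    site of any primer (including itself)."""
    out: list[AmpliconProduct] = []
    for tmpl in templates:
        sites = [
            (p_i, s)
            for p_i, primer in enumerate(primers)
            for s in find_binding_sites(primer, tmpl, max_mismatch, clamp_3prime)
        ]
        for i_fw, f in ((i, s) for i, s in sites if s.strand == "+"):
            for i_rv, r in ((i, s) for i, s in sites if s.strand == "-"):
                if r.start >= f.start and r.end >= f.end:
                    length = r.end - f.start + 1
                    if 0 < length <= max_len_bp:
                        out.append(
                            AmpliconProduct(tmpl.id, f.start, r.end, length,
                                            f.mismatches, r.mismatches)
                        )
    # identical coordinate spans from different primer pairings collapse to one band
    seen = set()
    uniq = []
    for p in sorted(out, key=lambda p: (p.template_id, p.start, p.end)):
        key = (p.template_id, p.start, p.end)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    return uniq


BAND_BD = 1080  # printed as both 1080 and 1081 bp; one band class
BAND_BT = 1192


def interpret_b_locus(
    bands: Iterable[int], genotype_id: str = "", tolerance_bp: int = 5
) -> MarkerCall:
    """Interpret multiplex band sizes as a B-locus genotype and chemotype class.

    {1192} -> B_T/B_T (chemotype I); {1080} -> B_D/B_D (chemotype III/IV/V,
    indistinct); both -> B_T/B_D (chemotype II); none -> no-call.  Bands are
    matched to the two targets within ``tolerance_bp`` (the B_D band is printed
    as both 1080 and 1081 bp and treated as one class).
    """
    bands = frozenset(int(b) for b in bands)

    def is_bd(b: int) -> bool:
        return min(abs(b - BAND_BD), abs(b - BAND_BD - 1)) <= tolerance_bp

    def is_bt(b: int) -> bool:
        return abs(b - BAND_BT) <= tolerance_bp

    has_bd = any(is_bd(b) for b in bands)
    has_bt = any(is_bt(b) for b in bands)
    unmatched = [b for b in bands if not (is_bd(b) or is_bt(b))]
    reason = ""
    if unmatched:
        reason = f"band(s) {sorted(unmatched)} match neither {BAND_BD} nor {BAND_BT}"
    if has_bd and has_bt:
        return MarkerCall(genotype_id, bands, BLocus.BT_BD, Chemotype.II, reason)
    if has_bt:
        return MarkerCall(genotype_id, bands, BLocus.BT_BT, Chemotype.I, reason)
    if has_bd:
        return MarkerCall(genotype_id, bands, BLocus.BD_BD, Chemotype.III_IV_V, reason)
    return MarkerCall(
        genotype_id, bands, BLocus.no_call, Chemotype.undetermined,
        reason or "no band within tolerance of either target",
    )


def primer_tm(primer: str) -> float:
    """Rough melting temperature for reporting only (never a filter).

    Wallace rule 2(A+T) + 4(G+C) under 14 nt; 64.9 + 41*(GC - 16.4)/N otherwise.
    """
    primer = primer.upper()
    n = len(primer)
    gc = sum(primer.count(b) for b in "GC")
    at = sum(primer.count(b) for b in "AT")
    if n < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def validate_primer_specificity(
    pair: PrimerPair,
    positive_templates: Sequence[SequenceRecord],
    negative_templates: Sequence[SequenceRecord],
    max_mismatch: int = 2,
    clamp_3prime: int = 3,
    max_len_bp: int = 5000,
) -> SpecificityReport:
    """Executable form of the wet-lab primer validation.

    PASS iff the pair predicts at least one product on every positive template
    and none on any negative template.  A Tm uniqueness note stands in for the
    melting-curve step, report-only.
    """
    if not positive_templates or not negative_templates:
        raise ValueError("need at least one positive and one negative template")
    products: dict[str, list[AmpliconProduct]] = {}
    failures: list[str] = []
    for tmpl in positive_templates:
        prods = predict_products(pair, [tmpl], max_len_bp, max_mismatch, clamp_3prime)
        products[tmpl.id] = prods
        if not prods:
            failures.append(f"no product on positive template {tmpl.id}")
    for tmpl in negative_templates:
        prods = predict_products(pair, [tmpl], max_len_bp, max_mismatch, clamp_3prime)
        products[tmpl.id] = prods
        if prods:
            failures.append(f"product on negative template {tmpl.id}")
    tm_f, tm_r = primer_tm(pair.fw), primer_tm(pair.rv)
    note = (
        f"estimated Tm fw {tm_f:.1f} C / rv {tm_r:.1f} C "
        f"(delta {abs(tm_f - tm_r):.1f} C); single-amplicon check is in-silico only"
    )
    return SpecificityReport(pair.name, not failures, products, failures, tm_f, tm_r, note)


def products_to_frame(products: Sequence[AmpliconProduct]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"template_id": p.template_id, "start": p.start, "end": p.end,
             "length_bp": p.length_bp, "fw_mismatches": p.fw_mismatches,
             "rv_mismatches": p.rv_mismatches}
            for p in products
        ],
        columns=["template_id", "start", "end", "length_bp",
                 "fw_mismatches", "rv_mismatches"],
    )


def marker_calls_to_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"genotype_id": c.genotype_id,
             "bands": ",".join(str(b) for b in sorted(c.bands)),
             "b_locus": c.b_locus.value, "chemotype_class": c.chemotype_class.value,
             "reason": c.reason}
            for c in calls
        ],
        columns=["genotype_id", "bands", "b_locus", "chemotype_class", "reason"],
    )
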