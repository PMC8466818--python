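"""Synthetic gene families and qPCR plates with known ground truth.

The generators emulate the structure of the cannabinoid synthase study system:

* a family of co-linear single-exon cds (default 1638 nt = 545 codons + stop,
  the THCAS/CBCAS length) split into clades by a handful of clade-fixed
  diagnostic substitutions (defaults at cds positions 13, 18 and 1628, with the
  alleles readable off the published cds primer sequences), plus 3-8 private
  substitutions per sequence and an optional fraction of pseudogenes carrying
  an internal stop;
* qPCR plates: 5-point 1:4 dilution standards and 3 biological x 3 technical
  replicate unknowns, with Cq generated from true per-genotype expression under
  the exponential-phase idealization Cq = intercept - log10(q)/log10(1+E) plus
  Gaussian Cq noise.

Every output is paired with a truth table sufficient to score the downstream
calls, and every generator is seed-deterministic (identical bytes).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pcr import PrimerPair
from .seq import STOP_CODONS, Role, SequenceRecord

# diagnostic alleles at cds positions 13/18/1628, as carried by the published
# cds primer footprints (CBCAS fw covers cds 1-18, its rv covers 1628-1638;
# the THCAS pair covers the same positions with the alternative alleles)
CBCAS_DIAGNOSTIC: list[tuple[int, str]] = [(13, "A"), (18, "C"), (1628, "G")]
THCAS_DIAGNOSTIC: list[tuple[int, str]] = [(13, "G"), (18, "T"), (1628, "A")]

#: residues whose codons the generator never touches (activity-critical set)
DEFAULT_PROTECTED_CODONS: list[int] = [110, 111, 112, 113, 114, 176]

_BASES = "ACGT"


@dataclass
class CladeSpec:
    name: str
    n_sequences: int
    diagnostic: list[tuple[int, str]]
    private_snps_range: tuple[int, int] = (3, 8)


@dataclass
class FamilyConfig:
    ancestor_length_nt: int = 1638
    clades: list[CladeSpec] = field(
        default_factory=lambda: [
            CladeSpec("CBCAS", 10, list(CBCAS_DIAGNOSTIC)),
            CladeSpec("THCAS", 10, list(THCAS_DIAGNOSTIC)),
        ]
    )
    pseudogene_fraction: float = 0.0
    protected_codons: list[int] = field(default_factory=lambda: list(DEFAULT_PROTECTED_CODONS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length_nt % 3 != 0 or self.ancestor_length_nt < 30:
            raise ValueError("ancestor_length_nt must be >= 30 and divisible by 3")
        if not (0.0 <= self.pseudogene_fraction <= 1.0):
            raise ValueError("pseudogene_fraction must be in [0, 1]")
        seen: set[int] = set()
        for clade in self.clades:
            for pos, allele in clade.diagnostic:
                if not (1 <= pos <= self.ancestor_length_nt):
                    raise ValueError(
                        f"diagnostic position {pos} beyond ancestor length "
                        f"{self.ancestor_length_nt}"
                    )
                if allele not in _BASES:
                    raise ValueError(f"diagnostic allele {allele!r} must be one of ACGT")
        # positions may be shared across clades (that is the point); uniqueness
        # is required within a clade only
        for clade in self.clades:
            pos = [p for p, _ in clade.diagnostic]
            if len(set(pos)) != len(pos):
                raise ValueError(f"clade {clade.name}: duplicate diagnostic positions")


@dataclass
class TruthTable:
    """Ground truth for a generated family: enough to audit every call."""

    per_sequence: pd.DataFrame
    diagnostics: dict[str, list[tuple[int, str]]]
    snp_sets: dict[str, list[tuple[int, str, str]]]  # seq_id -> (pos, clade_ref_base, alt)
    clade_references: dict[str, SequenceRecord]
    config: FamilyConfig


def _random_cds(rng: np.random.Generator, length_nt: int) -> list[str]:
    """A complete cds as a base list: ATG + random non-stop codons + TAA."""
    bases = ["A", "T", "G"]
    n_codons = length_nt // 3
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3))
            if codon not in STOP_CODONS:
                break
        bases.extend(codon)
    bases.extend("TAA")
    return bases


def _mutate_no_stop(
    seq: list[str], pos0: int, rng: np.random.Generator
) -> str | None:
    """Substitute at 0-based ``pos0`` with an allele that does not create an
    in-frame stop; returns the new base or None if impossible."""
    codon_start = (pos0 // 3) * 3
    cur = seq[pos0]
    candidates = [b for b in _BASES if b != cur]
    rng.shuffle(candidates)
    for alt in candidates:
        codon = seq[codon_start : codon_start + 3]
        codon[pos0 - codon_start] = alt
        if "".join(codon) not in STOP_CODONS:
            return alt
    return None


def _distinct_base(
    seq: list[str], pos0: int, taken: set[str], rng: np.random.Generator
) -> str:
    """A base at ``pos0`` distinct from ``taken`` that creates no in-frame stop."""
    codon_start = (pos0 // 3) * 3
    candidates = [b for b in _BASES if b not in taken]
    rng.shuffle(candidates)
    for alt in candidates:
        codon = seq[codon_start : codon_start + 3]
        codon[pos0 - codon_start] = alt
        if "".join(codon) not in STOP_CODONS:
            return alt
    raise ValueError(f"no stop-free distinct base available at position {pos0 + 1}")


def simulate_gene_family(cfg: FamilyConfig) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate a diagnostic-SNP-structured gene family with ground truth.

    A random ancestor cds is drawn; each clade applies its diagnostic alleles
    to the ancestor; each sequence then receives k ~ Uniform(min, max) private
    substitutions placed uniformly outside forbidden zones (diagnostic
    positions of any clade, protected codons, start and stop codons) and never
    creating an in-frame stop.  ``pseudogene_fraction`` of each clade's
    sequences additionally get one internal stop codon.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestor_length_nt
    ancestor = _random_cds(rng, L)

    forbidden: set[int] = set()  # 0-based nt positions private SNPs must avoid
    for clade in cfg.clades:
        forbidden.update(p - 1 for p, _ in clade.diagnostic)
    for codon in cfg.protected_codons:
        forbidden.update(range(3 * (codon - 1), 3 * codon))
    forbidden.update(range(0, 3))
    forbidden.update(range(L - 3, L))
    allowed = np.array(sorted(set(range(L)) - forbidden))

    protected_codon_set = set(cfg.protected_codons) | {1, L // 3}
    diag_codons = {
        (p - 1) // 3 + 1 for clade in cfg.clades for p, _ in clade.diagnostic
    }

    records: list[SequenceRecord] = []
    rows: list[dict] = []
    snp_sets: dict[str, list[tuple[int, str, str]]] = {}
    clade_refs: dict[str, SequenceRecord] = {}

    for clade in cfg.clades:
        ref = list(ancestor)
        for pos, allele in clade.diagnostic:
            ref[pos - 1] = allele
        clade_refs[clade.name] = SequenceRecord(
            id=f"{clade.name}_ref", seq="".join(ref), role=Role.reference
        )
        n_pseudo = int(round(cfg.pseudogene_fraction * clade.n_sequences))
        pseudo_idx = set(
            rng.choice(clade.n_sequences, size=n_pseudo, replace=False).tolist()
        ) if n_pseudo else set()

        lo, hi = clade.private_snps_range
        for i in range(clade.n_sequences):
            seq = list(ref)
            k = int(rng.integers(lo, hi + 1))
            chosen: list[int] = []
            snps: list[tuple[int, str, str]] = []
            attempts = 0
            while len(chosen) < k and attempts < 50 * k + 100:
                attempts += 1
                pos0 = int(rng.choice(allowed))
                if pos0 in chosen:
                    continue
                alt = _mutate_no_stop(seq, pos0, rng)
                if alt is None:
                    continue
                seq[pos0] = alt
                chosen.append(pos0)
                snps.append((pos0 + 1, ref[pos0], alt))
            snps.sort()

            pseudo_stop: int | None = None
            if i in pseudo_idx:
                internal = [
                    c for c in range(2, L // 3)
                    if c not in protected_codon_set and c not in diag_codons
                ]
                codon = int(rng.choice(internal))
                stop = str(rng.choice(sorted(STOP_CODONS)))
                seq[3 * (codon - 1) : 3 * codon] = list(stop)
                pseudo_stop = codon

            seq_id = f"{clade.name}_{i + 1:03d}"
            records.append(SequenceRecord(id=seq_id, seq="".join(seq), role=Role.query))
            snp_sets[seq_id] = snps
            rows.append(
                {
                    "seq_id": seq_id,
                    "clade": clade.name,
                    "status": "pseudogene" if pseudo_stop else "complete",
                    "n_private_snps": len(snps),
                    "snps": ";".join(f"{p}:{r}>{a}" for p, r, a in snps),
                    "pseudo_stop_codon": pseudo_stop if pseudo_stop else 0,
                }
            )

    truth = TruthTable(
        per_sequence=pd.DataFrame(rows),
        diagnostics={c.name: list(c.diagnostic) for c in cfg.clades},
        snp_sets=snp_sets,
        clade_references=clade_refs,
        config=cfg,
    )
    return records, truth


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

@dataclass
class PlateTruth:
    expression: pd.DataFrame  # genotype, gene, true_quantity (NaN = absent)
    efficiencies: dict[str, float]
    intercepts: dict[str, float]
    noise_sd: float


def simulate_qpcr_plate(
    design: dict[str, dict[str, float | None]],
    efficiencies: dict[str, float],
    noise_sd: float = 0.15,
    seed: int | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    intercepts: dict[str, float] | None = None,
    n_standard_points: int = 5,
    dilution: float = 4.0,
) -> tuple[pd.DataFrame, PlateTruth]:
    """Simulate a long-format qPCR plate from known per-genotype expression.

    ``design`` maps genotype -> gene -> true relative quantity (None = gene
    absent in that genotype, yielding undetermined Cq).  Standards are a
    ``n_standard_points``-point 1:``dilution`` series (top quantity 1.0);
    all Cq values follow Cq = intercept - log10(q)/log10(1 + E) + N(0, noise_sd).
    """
    for genotype, genes in design.items():
        for gene, expr in genes.items():
            if expr is not None and not expr > 0:
                raise ValueError(f"{genotype}/{gene}: expression must be > 0 or None")
    genes = sorted({g for genes in design.values() for g in genes})
    for gene in genes:
        e = efficiencies.get(gene)
        if e is None or not (0.0 < e <= 1.2):
            raise ValueError(f"{gene}: efficiency must be in (0, 1.2]")
    intercepts = dict(intercepts or {})
    for gene in genes:
        intercepts.setdefault(gene, 24.0)

    rng = np.random.default_rng(seed)

    def cq_of(q: float, gene: str) -> float:
        base = intercepts[gene] - math.log10(q) / math.log10(1.0 + efficiencies[gene])
        return base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)

    rows: list[dict] = []
    for gene in genes:
        for point in range(n_standard_points):
            q = dilution ** (-point)
            rows.append(
                {
                    "sample_id": f"std_{gene}_{point + 1}",
                    "genotype": "standard",
                    "gene": gene,
                    "bio_rep": 0,
                    "tech_rep": 1,
                    "cq": cq_of(q, gene),
                    "is_standard": True,
                    "log10_quantity": math.log10(q),
                }
            )
    expr_rows = []
    for genotype in design:
        for gene in genes:
            expr = design[genotype].get(gene)
            expr_rows.append(
                {"genotype": genotype, "gene": gene,
                 "true_quantity": float("nan") if expr is None else float(expr)}
            )
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    rows.append(
                        {
                            "sample_id": f"{genotype}_b{bio}",
                            "genotype": genotype,
                            "gene": gene,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "cq": float("nan") if expr is None else cq_of(expr, gene),
                            "is_standard": False,
                            "log10_quantity": float("nan"),
                        }
                    )
    plate = pd.DataFrame(rows)
    truth = PlateTruth(pd.DataFrame(expr_rows), dict(efficiencies), intercepts, noise_sd)
    return plate, truth


# ---------------------------------------------------------------------------
# study fixture (printed tables as data)
# ---------------------------------------------------------------------------

#: Table of the 13 genotypes: name, chemotype, marker phenotype, sampling
#: (days after sowing; days from onset of flowering for the two medical
#: varieties) and cannabinoid content metadata (% dry weight; fixture only).
GENOTYPE_TABLE: list[tuple] = [
    ("Santhica 27", "IV", "BD/BD", 123, "0.26", "1.55", "0.04", "<LOD"),
    ("Carmagnola", "III", "BD/BD", 151, "5.32", "0.28", "0.16", "<LOQ"),
    ("Bernabeo", "IV", "BD/BD", 151, "0.74", "2.69", "0.04", "<LOQ"),
    ("Carmaleonte", "III", "BD/BD", 123, "1.92", "0.10", "0.10", "<LOQ"),
    ("CS", "III", "BD/BD", 151, "5.49", "0.20", "0.17", "<LOQ"),
    ("Ermo", "V", "BD/BD", 151, "0.05", "<LOD", "<LOD", "<LOD"),
    ("Fibrante", "III", "BD/BD", 151, "3.61", "0.09", "0.13", "<LOQ"),
    ("Fibranova", "III", "BD/BD", 151, "2.34", "0.10", "0.07", "<LOQ"),
    ("Eletta Campana", "III", "BD/BD", 151, "3.85", "0.17", "0.11", "<LOQ"),
    ("Codimono", "III", "BD/BD", 123, "4.02", "0.15", "0.14", "<LOQ"),
    ("Futura 75", "III", "BD/BD", 123, "2.34", "0.12", "0.07", "<LOD"),
    ("CINBOL", "I", "BT/BT", 50, "0.01", "0.37", "3.71", "0.01"),
    ("CINRO", "II", "BT/BD", 50, "2.43", "0.27", "1.57", "0.02"),
]

#: Published full-cds primer pairs (amplicon lengths in bp).
CDS_PRIMERS: list[dict] = [
    {"name": "CBCAS-cds", "fw": "TGAAGAAAAATGAATTGCTCAACATTC",
     "rv": "ACATAGTATGGGTAGATAATTAATGATGAC", "expected_len_bp": 1666},
    {"name": "THCAS-cds", "fw": "ATGAATTGCTCAGCATTTTCCTT",
     "rv": "ATGATGATGCGGTGGAAGA", "expected_len_bp": 1635},
    {"name": "CBDAS-cds", "fw": "ATGAAGTGCTCAACATTCTCCTT",
     "rv": "TTAATGACGATGCCGTGGAA", "expected_len_bp": 1635},
]

#: Published RT-qPCR primer pairs with amplicon length, R2, efficiency,
#: annealing temperature and usage concentration.
QPCR_PRIMERS: list[dict] = [
    {"name": "CBDAS-RTqPCR", "fw": "GCAATACACACTTACTTCTCTTCAGTTTTC",
     "rv": "ACGTAGTCTAACTTATCTTGAAAGCAC", "expected_len_bp": 241,
     "r_squared": 0.99, "efficiency": 1.04, "ta_celsius": 61.5, "conc_um": 0.075},
    {"name": "THCAS-RTqPCR", "fw": "AAAACTTCCTTAAATGCTTCTCAA",
     "rv": "TAAAATAGTTGCTTGGATATGGGAGTT", "expected_len_bp": 198,
     "r_squared": 0.94, "efficiency": 0.8, "ta_celsius": 58.0, "conc_um": 0.175},
    {"name": "CBCAS-RTqPCR", "fw": "GCTCACGACTCACTTCAGAACTAG",
     "rv": "GTAGAAGATGGTTGTATCAATCCAGCTC", "expected_len_bp": 198,
     "r_squared": 0.98, "efficiency": 1.01, "ta_celsius": 62.0, "conc_um": 0.1},
]


def default_expression_design() -> dict[str, dict[str, float | None]]:
    """Per-genotype true expression for plate simulation.

    Target-gene levels follow the reported relative-quantitation pattern
    (THCAS detectable only in the two medical varieties, CBDAS absent in the
    chemotype-I variety, CBCAS low everywhere); the three candidate reference
    genes are flat at 1.0 by construction.
    """
    thcas = {"CINBOL": 17.80, "CINRO": 1.32}
    cbdas = {
        "Santhica 27": 0.02, "Carmagnola": 1.81, "Bernabeo": 0.55,
        "Carmaleonte": 0.60, "CS": 1.50, "Ermo": 0.90, "Fibrante": 1.20,
        "Fibranova": 0.75, "Eletta Campana": 1.00, "Codimono": 1.30,
        "Futura 75": 0.28, "CINRO": 4.90, "CINBOL": None,
    }
    cbcas = {
        "Santhica 27": 0.04, "Carmagnola": 0.90, "Bernabeo": 0.70,
        "Carmaleonte": 0.05, "CS": 0.80, "Ermo": 0.05, "Fibrante": 0.75,
        "Fibranova": 0.06, "Eletta Campana": 0.06, "Codimono": 0.70,
        "Futura 75": 0.05, "CINRO": 0.05, "CINBOL": 0.06,
    }
    design: dict[str, dict[str, float | None]] = {}
    for row in GENOTYPE_TABLE:
        g = row[0]
        design[g] = {
            "THCAS": thcas.get(g),
            "CBDAS": cbdas.get(g),
            "CBCAS": cbcas.get(g),
            "CsActin": 1.0,
            "CsRAN": 1.0,
            "CsClathrin": 1.0,
        }
    return design


DEFAULT_EFFICIENCIES: dict[str, float] = {
    "CBDAS": 1.04, "THCAS": 0.8, "CBCAS": 1.01,
    "CsActin": 0.95, "CsRAN": 1.0, "CsClathrin": 0.98,
}


def make_paper_fixture() -> dict:
    """Bundle of the study's printed metadata plus the default family config.

    Contains the 13-genotype table, the cds and RT-qPCR primer fixtures, the
    default two-clade family configuration (diagnostics at 13/18/1628) and the
    default expression design / efficiencies for plate simulation.
    """
    genotypes = pd.DataFrame(
        GENOTYPE_TABLE,
        columns=["genotype", "chemotype", "marker_phenotype", "sampling",
                 "cbd_pct", "cbg_pct", "thc_pct", "cbc_pct"],
    )
    cds_primers = [PrimerPair(**d) for d in CDS_PRIMERS]
    qpcr_primers = [
        PrimerPair(name=d["name"], fw=d["fw"], rv=d["rv"],
                   expected_len_bp=d["expected_len_bp"],
                   ta_celsius=d["ta_celsius"], conc_um=d["conc_um"])
        for d in QPCR_PRIMERS
    ]
    return {
        "genotypes": genotypes,
        "cds_primers": cds_primers,
        "qpcr_primers": qpcr_primers,
        "qpcr_primer_table": pd.DataFrame(QPCR_PRIMERS),
        "family_config": FamilyConfig(),
        "expression_design": default_expression_design(),
        "efficiencies": dict(DEFAULT_EFFICIENCIES),
    }


# ---------------------------------------------------------------------------
# synthetic three-gene template panel (for in-silico PCR and genotyping)
# ---------------------------------------------------------------------------

# published primer footprints inside the cds (1-based, end-inclusive)
_CBCAS_START = "ATGAATTGCTCAACATTC"  # cds 1-18 (from CBCAS-cds fw)
_CBCAS_END = "GTCATCATTAA"  # cds 1628-1638 (from CBCAS-cds rv, revcomp)
_THCAS_START = "ATGAATTGCTCAGCATTTTCCTT"  # cds 1-23 (THCAS-cds fw)
_THCAS_END = "TCTTCCACCGCATCATCAT"  # cds 1617-1635 (THCAS-cds rv, revcomp)
_CBDAS_START = "ATGAAGTGCTCAACATTCTCCTT"  # cds 1-23 (CBDAS-cds fw)
_CBDAS_END = "TTCCACGGCATCGTCATTAA"  # cds 1616-1635 (CBDAS-cds rv, revcomp)

_CBCAS_UPSTREAM = "TGAAGAAAA"  # 9 nt ahead of ATG, from the CBCAS-cds fw primer
_CBCAS_DOWNSTREAM = "TTATCTACCCATACTATGT"  # 19 nt after the stop, from the rv

# synthetic marker layout: shared reverse-primer region and the two specific
# forward-primer regions, chosen to give the 1080- and 1192-bp marker bands
_MARKER_RV_REGION = (1500, 1519)
_MARKER_FW_THCAS = (328, 347)  # 1519 - 1192 + 1 = 328
_MARKER_FW_CBDAS = (440, 459)  # 1519 - 1080 + 1 = 440


def _overwrite(seq: list[str], start_1b: int, text: str) -> None:
    seq[start_1b - 1 : start_1b - 1 + len(text)] = list(text)


def make_template_panel(seed: int = 0) -> dict:
    """Synthetic three-gene template panel carrying the published primer sites.

    Builds CBCAS and THCAS cds (1638 nt) and a CBDAS cds (1635 nt) from one
    ancestor, overwrites the published primer footprints of each gene, injects
    clade-level differences (~60 between the THCAS-like and CBCAS-like bodies,
    ~16% divergence for CBDAS) while keeping a shared marker region, and adds
    genomic templates with the flanking bases the CBCAS pair requires.  Also
    derives a synthetic three-primer B-locus marker system (bands 1080 / 1192)
    and per-genotype template sets for the 13 study genotypes.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    L = 1638
    ancestor = _random_cds(rng, L)

    shared_lo, shared_hi = _MARKER_RV_REGION
    keep = set(range(shared_lo - 1, shared_hi))  # marker region: identical everywhere

    cbcas = list(ancestor)
    _overwrite(cbcas, 1, _CBCAS_START)
    _overwrite(cbcas, 1628, _CBCAS_END)

    thcas = list(ancestor)
    _overwrite(thcas, 1, _THCAS_START)
    _overwrite(thcas, 1617, _THCAS_END)
    _overwrite(thcas, 1636, "TAA")

    # clade-level differences between the THCAS and CBCAS bodies (~96% identity
    # margin in miniature); always include the marker-forward 3' anchors so the
    # specific primers discriminate by their 3' clamp
    body = [i for i in range(23, 1615) if i not in keep]
    n_diff = 60
    diff_positions = set(int(p) for p in rng.choice(body, size=n_diff, replace=False))
    for pos0 in sorted(diff_positions):
        alt = _mutate_no_stop(thcas, pos0, rng)
        if alt is not None:
            thcas[pos0] = alt

    # CBDAS: drop one codon after the marker region (1638 -> 1635), overwrite
    # its footprints, then diverge ~16% of the remaining body
    cbdas = list(ancestor)
    del cbdas[1557:1560]  # codon 520 (nt 1558-1560), downstream of the marker region
    _overwrite(cbdas, 1, _CBDAS_START)
    _overwrite(cbdas, 1616, _CBDAS_END)
    cb_body = [
        i for i in range(23, 1612)
        if i not in keep
    ]
    n_div = int(0.16 * len(cb_body))
    div_positions = set(int(p) for p in rng.choice(cb_body, size=n_div, replace=False))
    for pos0 in sorted(div_positions):
        alt = _mutate_no_stop(cbdas, pos0, rng)
        if alt is not None:
            cbdas[pos0] = alt

    # the marker-forward 3'-anchor bases must be pairwise distinct across the
    # three genes so each specific primer discriminates by its 3' clamp
    for pos0 in (_MARKER_FW_THCAS[1] - 1, _MARKER_FW_CBDAS[1] - 1):
        taken = {cbcas[pos0]}
        for seq in (thcas, cbdas):
            alt = _distinct_base(seq, pos0, taken, rng)
            seq[pos0] = alt
            taken.add(alt)

    cbcas_cds = SequenceRecord("CBCAS_cds", "".join(cbcas), role=Role.reference)
    thcas_cds = SequenceRecord("THCAS_cds", "".join(thcas), role=Role.reference)
    cbdas_cds = SequenceRecord("CBDAS_cds", "".join(cbdas), role=Role.reference)

    def pad(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    cbcas_genomic = SequenceRecord(
        "CBCAS_genomic",
        pad(25) + _CBCAS_UPSTREAM + cbcas_cds.seq + _CBCAS_DOWNSTREAM + pad(25),
        role=Role.template,
    )
    thcas_genomic = SequenceRecord(
        "THCAS_genomic", pad(30) + thcas_cds.seq + pad(30), role=Role.template
    )
    cbdas_genomic = SequenceRecord(
        "CBDAS_genomic", pad(30) + cbdas_cds.seq + pad(30), role=Role.template
    )

    # synthetic three-primer B-locus marker (bands 1080 and 1192)
    from Bio.Seq import Seq as _Seq

    rv_common = str(_Seq(thcas_cds.seq[shared_lo - 1 : shared_hi]).reverse_complement())
    fw_thcas = thcas_cds.seq[_MARKER_FW_THCAS[0] - 1 : _MARKER_FW_THCAS[1]]
    fw_cbdas = cbdas_cds.seq[_MARKER_FW_CBDAS[0] - 1 : _MARKER_FW_CBDAS[1]]
    marker_primers = {"fw_thcas": fw_thcas, "fw_cbdas": fw_cbdas, "rv_common": rv_common}

    genotype_templates: dict[str, list[SequenceRecord]] = {}
    for row in GENOTYPE_TABLE:
        genotype, chemotype = row[0], row[1]
        if chemotype == "I":
            tmpl = [thcas_genomic, cbcas_genomic]
        elif chemotype == "II":
            tmpl = [thcas_genomic, cbdas_genomic, cbcas_genomic]
        else:  # III / IV / V carry a functional CBDAS marker allele only
            tmpl = [cbdas_genomic, cbcas_genomic]
        genotype_templates[genotype] = tmpl

    return {
        "cbcas_cds": cbcas_cds,
        "thcas_cds": thcas_cds,
        "cbdas_cds": cbdas_cds,
        "cbcas_genomic": cbcas_genomic,
        "thcas_genomic": thcas_genomic,
        "cbdas_genomic": cbdas_genomic,
        "marker_primers": marker_primers,
        "genotype_templates": genotype_templates,
    }
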