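"""RT-qPCR relative quantification with the standard-curve method.

Per gene, a 5-point dilution series yields an OLS regression of Cq on
log10(quantity); amplification efficiency is E = 10^(-1/slope) - 1.  Unknown
Cq values (technical replicates averaged on the Cq scale) are interpolated to
quantities, the target quantity is normalized per biological replicate to the
geometric mean of the reference-gene quantities, and the genotype-level
Relative Quantitation (RQ, arbitrary units) is the mean over biological
replicates with SEM.  Reference-gene stability is ranked by a documented
two-score scheme (geNorm-style M and comparative delta-Ct SD, combined by
geometric mean of ranks).  Group comparisons use a two-sided pooled-variance
Student's t-test on log-transformed per-replicate RQ.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("cansynth")

PLATE_COLUMNS = [
    "sample_id", "genotype", "gene", "bio_rep", "tech_rep",
    "cq", "is_standard", "log10_quantity",
]


@dataclass
class QpcrWell:
    sample_id: str
    genotype: str
    gene: str
    replicate_bio: int
    replicate_tech: int
    cq: float | None  # None / NaN = undetermined ("n.d.")
    is_standard: bool = False
    standard_log10_quantity: float | None = None


@dataclass
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int


@dataclass
class RQResult:
    genotype: str
    gene: str
    rq: float
    sem: float
    n: int
    detected: bool
    rep_values: list[float] = field(default_factory=list)  # per-bio-replicate RQ
    p_vs_baseline: float | None = None
    stars: str | None = None


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate CSV (sample, genotype, gene, bio_rep, tech_rep,
    cq, is_standard, log10_quantity); empty cq cells become NaN."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    df["is_standard"] = df["is_standard"].astype(bool)
    return df


def amplification_efficiency(slope: float) -> float:
    """E = 10^(-1/slope) - 1; the per-cycle gain implied by a standard curve."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(points: Sequence[tuple[float, float]], gene: str = "") -> StandardCurve:
    """OLS of Cq on log10(quantity) over dilution-series points."""
    pts = [(float(x), float(y)) for x, y in points if not (math.isnan(y))]
    if len(pts) < 3:
        raise ValueError(f"{gene or 'curve'}: need >= 3 standard points")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise ValueError(f"{gene or 'curve'}: all standard quantities are equal")
    res = stats.linregress(xs, ys)
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=amplification_efficiency(float(res.slope)),
        n_points=len(pts),
    )


def fit_curves_from_plate(plate: pd.DataFrame) -> dict[str, StandardCurve]:
    """One standard curve per gene from the plate's standard wells."""
    curves: dict[str, StandardCurve] = {}
    std = plate[plate["is_standard"]]
    for gene, grp in std.groupby("gene"):
        pts = list(zip(grp["log10_quantity"], grp["cq"]))
        curves[str(gene)] = fit_standard_curve(pts, gene=str(gene))
    return curves


def interpolate_quantity(cq: float, curve: StandardCurve) -> float:
    """quantity = 10^((cq - intercept) / slope); NaN propagates as NaN."""
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return float("nan")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


# ---------------------------------------------------------------------------
# reference-gene stability (RefFinder stand-in)
# ---------------------------------------------------------------------------

def rank_reference_stability(
    plate: pd.DataFrame,
    candidate_genes: Sequence[str],
    curves: dict[str, StandardCurve] | None = None,
) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability across samples.

    Two scores are computed on per-sample (genotype x biological replicate,
    technical replicates averaged on Cq) expression values:

    * ``m_value`` — geNorm-style M: mean over partner genes of the SD across
      samples of the pairwise log2 expression ratio;
    * ``delta_ct_sd`` — comparative delta-Ct: mean over partners of the SD of
      the raw Cq difference.

    The final rank is the geometric mean of the two ranks (most stable first);
    ties break by delta_ct_sd, then name.  A gene missing (undetermined Cq) in
    more than half the samples is excluded with a warning.  When no curve is
    supplied for a gene, expression is taken as 2^(-Cq) (perfect efficiency).
    """
    if len(candidate_genes) < 2:
        raise ValueError("need >= 2 candidate reference genes")
    unknowns = plate[~plate["is_standard"]]
    cq = (
        unknowns[unknowns["gene"].isin(candidate_genes)]
        .groupby(["genotype", "bio_rep", "gene"])["cq"].mean().unstack("gene")
    )
    n_samples = len(cq)
    if n_samples < 3:
        raise ValueError("need >= 3 samples to rank stability")
    kept: list[str] = []
    for gene in candidate_genes:
        if gene not in cq.columns or cq[gene].isna().sum() > n_samples / 2:
            log.warning("stability ranking: %s missing in >50%% of samples; excluded", gene)
            continue
        kept.append(gene)
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable reference candidates")

    logq = pd.DataFrame(index=cq.index)
    for gene in kept:
        if curves and gene in curves:
            q = cq[gene].map(lambda c: interpolate_quantity(c, curves[gene]))
            logq[gene] = np.log2(q)
        else:
            logq[gene] = -cq[gene]  # log2 of 2^-Cq

    rows = []
    for gene in kept:
        m_parts, dct_parts = [], []
        for other in kept:
            if other == gene:
                continue
            m_parts.append(float((logq[gene] - logq[other]).std(ddof=1)))
            dct_parts.append(float((cq[gene] - cq[other]).std(ddof=1)))
        rows.append({"gene": gene, "m_value": float(np.mean(m_parts)),
                     "delta_ct_sd": float(np.mean(dct_parts))})
    df = pd.DataFrame(rows)
    df["rank_m"] = df["m_value"].rank(method="min")
    df["rank_dct"] = df["delta_ct_sd"].rank(method="min")
    df["stability_score"] = np.sqrt(df["rank_m"] * df["rank_dct"])
    df = df.sort_values(
        ["stability_score", "delta_ct_sd", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    df["final_rank"] = np.arange(1, len(df) + 1)
    return df[["gene", "m_value", "delta_ct_sd", "stability_score", "final_rank"]]


# ---------------------------------------------------------------------------
# relative quantitation
# ---------------------------------------------------------------------------

def compute_rq(
    plate: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    curves: dict[str, StandardCurve],
) -> list[RQResult]:
    """Normalized relative quantity of a target transcript per genotype.

    Per biological replicate: technical Cq replicates are averaged, quantities
    interpolated on each gene's standard curve, and
    RQ_rep = Q_target / geomean(Q_references).  The genotype RQ is the mean of
    RQ_rep with SEM = SD / sqrt(n).  A genotype with all target Cq undetermined
    is reported ``detected=False`` ("n.d."); a replicate with an undetected
    reference is dropped with a warning.
    """
    for gene in [target_gene, *reference_genes]:
        if gene not in curves:
            raise ValueError(f"no standard curve for gene {gene!r}")
    unknowns = plate[~plate["is_standard"]]
    cq = (
        unknowns[unknowns["gene"].isin([target_gene, *reference_genes])]
        .groupby(["genotype", "bio_rep", "gene"])["cq"].mean().unstack("gene")
    )
    results: list[RQResult] = []
    for genotype, grp in cq.groupby(level="genotype"):
        reps: list[float] = []
        any_target = False
        for _, row in grp.iterrows():
            q_refs = []
            ref_ok = True
            for ref in reference_genes:
                q = interpolate_quantity(row.get(ref, float("nan")), curves[ref])
                if math.isnan(q):
                    ref_ok = False
                    break
                q_refs.append(q)
            if not ref_ok:
                log.warning("compute_rq: %s replicate dropped (undetected reference)", genotype)
                continue
            q_t = interpolate_quantity(row.get(target_gene, float("nan")), curves[target_gene])
            if math.isnan(q_t):
                continue
            any_target = True
            reps.append(q_t / float(stats.gmean(q_refs)))
        if not any_target or not reps:
            results.append(RQResult(str(genotype), target_gene, float("nan"), float("nan"),
                                    0, False, []))
            continue
        arr = np.array(reps)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        results.append(
            RQResult(str(genotype), target_gene, float(arr.mean()), sem, len(arr), True,
                     [float(x) for x in reps])
        )
    return results


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_to_baseline(
    results: Sequence[RQResult], baseline_genotype: str
) -> list[RQResult]:
    """Two-sided pooled-variance Student's t-test of each genotype vs baseline.

    The test runs on natural-log-transformed per-replicate RQ values;
    zero/negative replicates are dropped from the transform with a warning.
    The baseline itself and undetected genotypes get no test.
    """
    baseline = next(
        (r for r in results if r.genotype == baseline_genotype and r.detected), None
    )
    if baseline is None:
        raise ValueError(f"baseline genotype {baseline_genotype!r} absent or undetected")
    base_logs = _log_reps(baseline)
    if len(base_logs) < 2:
        raise ValueError("baseline needs >= 2 usable replicates")
    out = []
    for r in results:
        r = RQResult(**{**r.__dict__})
        if r.detected and r.genotype != baseline_genotype:
            logs = _log_reps(r)
            if len(logs) >= 2:
                t, p = stats.ttest_ind(logs, base_logs, equal_var=True)
                r.p_vs_baseline = float(p)
                r.stars = _stars(float(p))
        out.append(r)
    return out


def _log_reps(r: RQResult) -> list[float]:
    logs = []
    for v in r.rep_values:
        if v > 0:
            logs.append(math.log(v))
        else:
            log.warning("%s/%s: non-positive RQ replicate dropped from log transform",
                        r.genotype, r.gene)
    return logs


def rq_to_frame(results: Sequence[RQResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "genotype": r.genotype, "gene": r.gene,
            "rq": "n.d." if not r.detected else round(r.rq, 6),
            "sem": "" if not r.detected else round(r.sem, 6),
            "n": r.n,
            "p_vs_baseline": "" if r.p_vs_baseline is None else r.p_vs_baseline,
            "stars": r.stars or "",
        })
    return pd.DataFrame(rows, columns=["genotype", "gene", "rq", "sem", "n",
                                       "p_vs_baseline", "stars"])
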