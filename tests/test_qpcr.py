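"""Standard curves, efficiency, stability ranking, RQ and significance."""
import math

import numpy as np
import pytest
from scipy import special

from cansynth import (
    RQResult,
    amplification_efficiency,
    compare_to_baseline,
    compute_rq,
    fit_curves_from_plate,
    fit_standard_curve,
    interpolate_quantity,
    rank_reference_stability,
    simulate_qpcr_plate,
)
from cansynth.qpcr import _stars


class TestStandardCurve:
    def test_exact_line_recovers_slope_and_unit_efficiency(self):
        points = [(x, -3.3219 * x + 30.0) for x in (0, -1, -2, -3, -4)]
        curve = fit_standard_curve(points, "g")
        assert abs(curve.slope + 3.3219) < 1e-9
        assert abs(curve.intercept - 30.0) < 1e-9
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert abs(curve.efficiency - 1.0) < 1e-3

    def test_printed_efficiency_example(self):
        # E = 10^(-1/slope) - 1 at slope -3.4531 gives 0.948
        assert abs(amplification_efficiency(-3.4531) - 0.948) < 1e-3

    def test_efficiency_decreasing_in_slope_magnitude(self):
        slopes = [-3.0, -3.2, -3.4, -3.6, -4.0]
        effs = [amplification_efficiency(s) for s in slopes]
        assert all(a > b for a, b in zip(effs, effs[1:]))

    def test_degenerate_quantities_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0, 20), (0, 21), (0, 22)])

    def test_interpolation_round_trip(self):
        curve = fit_standard_curve([(x, -3.5 * x + 28.0) for x in (0, -1, -2, -3, -4)])
        for q in (1.0, 0.25, 0.015625):
            cq = curve.intercept + curve.slope * math.log10(q)
            assert abs(interpolate_quantity(cq, curve) - q) < 1e-9
        assert interpolate_quantity(curve.intercept, curve) == pytest.approx(1.0)
        assert math.isnan(interpolate_quantity(float("nan"), curve))


class TestStabilityRanking:
    def _noisy_plate(self, sds, seed):
        design = {g: {gene: 1.0 for gene in sds} for g in "ABCDE"}
        plate, _ = simulate_qpcr_plate(
            design, {gene: 1.0 for gene in sds}, noise_sd=0.0, seed=seed
        )
        rng = np.random.default_rng(seed + 1_000_000)
        mask = ~plate["is_standard"]
        noise = plate.loc[mask, "gene"].map(sds).to_numpy() * rng.normal(
            size=mask.sum()
        )
        plate.loc[mask, "cq"] = plate.loc[mask, "cq"].to_numpy() + noise
        return plate

    def test_constant_gene_ranks_first(self):
        plate = self._noisy_plate({"steady": 0.0, "noisy1": 0.5, "noisy2": 0.7}, seed=0)
        ranking = rank_reference_stability(plate, ["steady", "noisy1", "noisy2"])
        assert ranking.iloc[0]["gene"] == "steady"

    def test_clearly_separated_noise_puts_quiet_gene_first(self):
        # the pairwise scores need >= 3 genes to carry information; with one
        # quiet gene against two noisy partners the quiet one ranks first
        plate = self._noisy_plate({"low": 0.05, "noisyA": 0.75, "noisyB": 0.8},
                                  seed=3)
        ranking = rank_reference_stability(plate, ["noisyB", "low", "noisyA"])
        assert ranking.iloc[0]["gene"] == "low"

    def test_identical_genes_tie_broken_deterministically(self):
        plate = self._noisy_plate({"a_gene": 0.3, "b_gene": 0.3}, seed=7)
        plate2 = plate.copy()
        # make b_gene an exact copy of a_gene so both scores tie
        a_cq = plate.loc[plate["gene"] == "a_gene", "cq"].to_numpy()
        plate2.loc[plate2["gene"] == "b_gene", "cq"] = a_cq
        ranking = rank_reference_stability(plate2, ["b_gene", "a_gene"])
        assert list(ranking["gene"]) == ["a_gene", "b_gene"]  # name breaks the tie


class TestComputeRq:
    def _plate(self, design, seed=0, noise=0.15, eff=None):
        eff = eff or {g: 1.0 for g in next(iter(design.values()))}
        return simulate_qpcr_plate(design, eff, noise_sd=noise, seed=seed)[0]

    def test_geometric_mean_normalization(self):
        # Q_target 10 vs refs {5, 20}: geomean 10 -> RQ 1.0
        design = {"G": {"T": 10.0, "R1": 5.0, "R2": 20.0}}
        plate = self._plate(design, noise=0.0)
        curves = fit_curves_from_plate(plate)
        (res,) = compute_rq(plate, "T", ["R1", "R2"], curves)
        assert res.rq == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_global_rescaling(self):
        base = {"G": {"T": 3.0, "R1": 1.0, "R2": 2.0}}
        scaled = {"G": {k: v * 37.5 for k, v in base["G"].items()}}
        curves_kwargs = dict(noise=0.0, seed=1)
        p1, p2 = self._plate(base, **curves_kwargs), self._plate(scaled, **curves_kwargs)
        r1 = compute_rq(p1, "T", ["R1", "R2"], fit_curves_from_plate(p1))[0].rq
        r2 = compute_rq(p2, "T", ["R1", "R2"], fit_curves_from_plate(p2))[0].rq
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_invariant_under_reference_exchange(self):
        design = {"G": {"T": 5.0, "R1": 0.5, "R2": 4.0}}
        plate = self._plate(design, noise=0.0)
        curves = fit_curves_from_plate(plate)
        a = compute_rq(plate, "T", ["R1", "R2"], curves)[0].rq
        b = compute_rq(plate, "T", ["R2", "R1"], curves)[0].rq
        assert a == pytest.approx(b, rel=1e-12)

    def test_parameter_recovery_across_true_ratios(self):
        # true RQ ratios 2 / 15 / 300 between two genotypes, 3x3 replicates,
        # Cq noise SD 0.15: mean recovered ratio within 20% over 100 seeds
        for true_ratio in (2.0, 15.0, 300.0):
            ratios = []
            for seed in range(100):
                design = {
                    "hi": {"T": true_ratio, "R1": 1.0, "R2": 1.0},
                    "lo": {"T": 1.0, "R1": 1.0, "R2": 1.0},
                }
                plate = self._plate(design, seed=seed, noise=0.15,
                                    eff={"T": 0.95, "R1": 1.0, "R2": 1.0})
                curves = fit_curves_from_plate(plate)
                res = {r.genotype: r.rq for r in compute_rq(plate, "T", ["R1", "R2"], curves)}
                ratios.append(res["hi"] / res["lo"])
            assert abs(np.mean(ratios) - true_ratio) / true_ratio < 0.20

    def test_undetected_target_reported_nd(self):
        design = {"G": {"T": None, "R1": 1.0, "R2": 1.0},
                  "H": {"T": 2.0, "R1": 1.0, "R2": 1.0}}
        plate = self._plate(design, noise=0.0)
        curves = fit_curves_from_plate(plate)
        by_geno = {r.genotype: r for r in compute_rq(plate, "T", ["R1", "R2"], curves)}
        assert not by_geno["G"].detected and math.isnan(by_geno["G"].rq)
        assert by_geno["H"].detected

    def test_missing_curve_rejected(self):
        design = {"G": {"T": 1.0, "R1": 1.0}}
        plate = self._plate(design, noise=0.0)
        curves = fit_curves_from_plate(plate)
        with pytest.raises(ValueError, match="R2"):
            compute_rq(plate, "T", ["R1", "R2"], curves)


class TestBaselineComparison:
    def _result(self, genotype, reps):
        arr = np.array(reps, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        return RQResult(genotype, "T", float(arr.mean()), sem, len(arr), True,
                        [float(x) for x in reps])

    def test_identical_groups_not_significant(self):
        results = [self._result("base", [1.0, 1.1, 0.9]),
                   self._result("same", [1.0, 1.1, 0.9])]
        out = compare_to_baseline(results, "base")
        same = next(r for r in out if r.genotype == "same")
        assert same.p_vs_baseline == pytest.approx(1.0)
        assert same.stars == "ns"

    def test_p_value_matches_closed_form_t_distribution(self):
        # log-values {0,0,0} vs {1, 1.1, 0.9}: pooled t with df = 4
        a = [math.exp(v) for v in (0.0, 0.0, 0.0)]
        b = [math.exp(v) for v in (1.0, 1.1, 0.9)]
        out = compare_to_baseline(
            [self._result("base", a), self._result("grp", b)], "base"
        )
        grp = next(r for r in out if r.genotype == "grp")
        x, y = np.zeros(3), np.array([1.0, 1.1, 0.9])
        sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
        t = (y.mean() - x.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_closed = 2 * (1 - special.stdtr(4, abs(t)))
        assert grp.p_vs_baseline == pytest.approx(p_closed, abs=1e-9)

    @pytest.mark.parametrize(
        "p,stars", [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0005, "***")]
    )
    def test_star_thresholds(self, p, stars):
        assert _stars(p) == stars

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compare_to_baseline([self._result("a", [1, 2, 3])], "zzz")
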