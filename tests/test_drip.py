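"""Tests for spike-in calibration, gene densities, metagenes, fork
orientation calls and DRIP-qPCR arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rloopkit import drip, simulate
from rloopkit.config import SimConfig
from rloopkit.drip import SpikeInCounts, StrandedCoverage


def _cov(counts, strand="W", fraction="IP", genome="experimental",
         bin_size=20, chrom="chrS"):
    counts = np.asarray(counts, dtype=float)
    starts = np.arange(len(counts)) * bin_size
    bins = pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + bin_size, "count": counts})
    return StrandedCoverage(sample_id="s", condition="c", treatment="mock",
                            fraction=fraction, genome=genome, strand=strand,
                            bins=bins)


class _Gene:
    def __init__(self, gene_id, chrom, start, end, strand):
        self.gene_id, self.chrom = gene_id, chrom
        self.start, self.end, self.strand = start, end, strand


class TestTemplateStrand:
    def test_convention(self):
        assert drip.template_strand("+") == "C"
        assert drip.template_strand("-") == "W"

    def test_invalid(self):
        with pytest.raises(ValueError):
            drip.template_strand(".")


class TestOccupancyRatio:
    def test_equal_fractions_give_one(self):
        a = SpikeInCounts("s", "input", 50, 1000)
        b = SpikeInCounts("s", "IP", 500, 10_000)
        assert drip.occupancy_ratio(a, b) == pytest.approx(1.0)

    def test_fivefold_enrichment_depletes_or(self):
        # IP spike fraction 5x the input fraction -> OR = 1/5
        inp = SpikeInCounts("s", "input", 50, 1000)
        ip = SpikeInCounts("s", "IP", 250, 1000)
        assert drip.occupancy_ratio(inp, ip) == pytest.approx(0.2)

    def test_depth_invariant(self):
        inp = SpikeInCounts("s", "input", 50, 1000)
        ip = SpikeInCounts("s", "IP", 20, 1000)
        ip2 = SpikeInCounts("s", "IP", 40, 2000)
        assert drip.occupancy_ratio(inp, ip) == drip.occupancy_ratio(inp, ip2)

    def test_zero_spike_errors(self):
        with pytest.raises(ValueError):
            drip.occupancy_ratio(SpikeInCounts("s", "input", 0, 1000),
                                 SpikeInCounts("s", "IP", 10, 1000))


class TestCalibrate:
    def test_worked_example(self):
        cov = drip.calibrate(_cov([100.0]), or_value=2.0, ip_total=1_000_000)
        # 100 reads / 1e6 total * 1e6 (per-million) * OR 2 = 200
        assert cov.bins["count"].iloc[0] == pytest.approx(200.0)

    def test_exact_depth_invariance(self):
        counts = np.array([5.0, 10.0, 0.0, 3.0])
        a = drip.calibrate(_cov(counts), or_value=1.7, ip_total=1000)
        b = drip.calibrate(_cov(counts * 2), or_value=1.7, ip_total=2000)
        assert np.allclose(a.bins["count"], b.bins["count"])

    def test_spike_genome_rejected(self):
        with pytest.raises(ValueError, match="experimental"):
            drip.calibrate(_cov([1.0], genome="spike"), 1.0, 100)

    def test_invalid_or_rejected(self):
        with pytest.raises(ValueError):
            drip.calibrate(_cov([1.0]), 0.0, 100)


class TestGeneDensity:
    def test_partial_bin_weighted_mean(self):
        # bins of 20 bp with counts 10/20/30; interval [10, 60) covers half of
        # bin0 (per-bp 0.5), all of bin1 (1.0/bp) and all of bin2 (1.5/bp):
        # (0.5*10 + 20 + 30) / 50 = 1.1 per bp
        cov = _cov([10.0, 20.0, 30.0])
        assert drip._interval_mean(cov.bins, "chrS", 10, 60) == pytest.approx(1.1)

    def test_full_bins_simple_mean(self):
        cov = _cov([10.0, 30.0])
        assert drip._interval_mean(cov.bins, "chrS", 0, 40) == pytest.approx(1.0)

    def test_missing_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            drip._interval_mean(_cov([1.0]).bins, "chrX", 0, 20)

    def test_template_assignment_and_specificity(self):
        tracks = {"W": _cov([0.0, 0.0, 0.0], strand="W"),
                  "C": _cov([20.0, 20.0, 20.0], strand="C")}
        plus = _Gene("g+", "chrS", 0, 60, "+")
        minus = _Gene("g-", "chrS", 0, 60, "-")
        d_plus = drip.gene_density(tracks, plus)
        d_minus = drip.gene_density(tracks, minus)
        # + gene: template is C (signal), specificity 1
        assert d_plus["template_density"] == pytest.approx(1.0)
        assert d_plus["specificity"] == pytest.approx(1.0)
        # - gene: template is W (empty), specificity 0
        assert d_minus["template_density"] == 0.0
        assert d_minus["specificity"] == 0.0

    def test_zero_both_strands_specificity_nan(self):
        tracks = {"W": _cov([0.0]), "C": _cov([0.0], strand="C")}
        d = drip.gene_density(tracks, _Gene("g", "chrS", 0, 20, "+"))
        assert np.isnan(d["specificity"])

    def test_rnase_h_sensitivity_values(self):
        assert drip.rnase_h_sensitivity(10.0, 1.0) == pytest.approx(0.9)
        assert drip.rnase_h_sensitivity(10.0, 0.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            drip.rnase_h_sensitivity(0.0, 1.0)

    def test_fold_change_values(self):
        assert drip.density_fold_change(4.0, 2.0) == pytest.approx(2.0)
        assert drip.density_fold_change(0.0, 0.0, pseudocount=1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            drip.density_fold_change(1.0, 0.0)


class TestMetagene:
    @staticmethod
    def _uniform_tracks(value=2.0, n_bins=200):
        return {"W": _cov([value] * n_bins, strand="W"),
                "C": _cov([value] * n_bins, strand="C")}

    def test_uniform_coverage_gives_flat_rows(self):
        genes = pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": "chrS",
            "start": [1000, 2000], "end": [1600, 2600],
            "strand": ["+", "-"],
        })
        mg = drip.metagene(self._uniform_tracks(), genes,
                           flank_bp=200, body_bins=10, bin_size=20)
        n_cols = 200 // 20 + 10 + 200 // 20
        assert mg["template"].shape == (2, n_cols)
        # uniform 2.0 per 20-bp bin -> 0.1 per bp everywhere
        assert np.allclose(mg["template"], 0.1)
        assert np.allclose(mg["nontemplate"], 0.1)

    def test_minus_strand_row_is_reversed(self):
        # signal ramps up along the chromosome; oriented 5'->3' a - gene
        # must show it ramping down
        counts = np.arange(200, dtype=float)
        tracks = {"W": _cov(counts), "C": _cov(counts, strand="C")}
        genes = pd.DataFrame({
            "gene_id": ["p", "m"], "chrom": "chrS",
            "start": [1000, 1000], "end": [1600, 1600], "strand": ["+", "-"],
        })
        mg = drip.metagene(tracks, genes, flank_bp=200, body_bins=10)
        ids = mg["gene_ids"]
        row_p = mg["template"][ids.index("p")]
        row_m = mg["template"][ids.index("m")]
        assert np.all(np.diff(row_p) > 0)
        assert np.all(np.diff(row_m) < 0)
        assert np.allclose(row_m, row_p[::-1])

    def test_rows_sorted_by_body_density_descending(self):
        n_bins = 200
        counts_w = np.zeros(n_bins)
        counts_w[50:60] = 5.0    # gene "hot" body
        counts_w[100:110] = 1.0  # gene "cold" body
        tracks = {"W": _cov(counts_w), "C": _cov(np.zeros(n_bins), strand="C")}
        genes = pd.DataFrame({
            "gene_id": ["cold", "hot"], "chrom": "chrS",
            "start": [2000, 1000], "end": [2200, 1200], "strand": ["-", "-"],
        })
        mg = drip.metagene(tracks, genes, flank_bp=100, body_bins=10)
        assert mg["gene_ids"] == ["hot", "cold"]


class TestOkseqSlope:
    def test_exact_line_recovered(self):
        pos = np.arange(0, 1000, 100)
        profile = pd.DataFrame({"chrom": "chrS", "position": pos,
                                "signal": 0.003 * pos + 1.0})
        slope, se = drip.okseq_slope(profile, "chrS", 0, 1000)
        assert slope == pytest.approx(0.003)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_errors(self):
        profile = pd.DataFrame({"chrom": "chrS", "position": [0, 100],
                                "signal": [0.0, 1.0]})
        with pytest.raises(ValueError):
            drip.okseq_slope(profile, "chrS", 0, 1000)

    def test_simulated_intervals_recover_truth_slopes(self, small_config):
        profile, truth = simulate.gen_okseq(small_config)
        for row in truth.head(4).itertuples():
            slope, _ = drip.okseq_slope(profile, row.chrom, row.start, row.end)
            assert slope * 1000 == pytest.approx(row.slope_per_kb, rel=1e-9)


class TestClassifyOrientation:
    @pytest.mark.parametrize("slope,strand,expected", [
        (1.0, "+", "CD"), (1.0, "-", "HO"), (-1.0, "+", "HO"), (-1.0, "-", "CD"),
    ])
    def test_definition_table(self, slope, strand, expected):
        res = drip.classify_orientation(slope, 0.01, strand)
        assert res["orientation"] == expected
        assert res["fork_direction"] == ("right" if slope > 0 else "left")

    def test_convention_flip_swaps_calls(self):
        a = drip.classify_orientation(1.0, 0.01, "+")
        b = drip.classify_orientation(
            1.0, 0.01, "+", sign_convention="positive_slope_means_leftward")
        assert a["orientation"] == "CD" and b["orientation"] == "HO"
        assert b["fork_direction"] == "left"

    def test_ambiguity_rule(self):
        # |slope| < k*SE -> ambiguous; equality is decisive
        assert drip.classify_orientation(0.1, 0.06, "+")["orientation"] == "ambiguous"
        assert drip.classify_orientation(0.12, 0.06, "+")["orientation"] == "CD"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            drip.classify_orientation(1.0, 0.1, "+", sign_convention="nope")
        with pytest.raises(ValueError):
            drip.classify_orientation(1.0, 0.1, ".")


class TestQpcr:
    def test_equal_ct_returns_input_fraction(self):
        assert drip.qpcr_percent_ip(25.0, 25.0) == pytest.approx(5.0)

    def test_one_cycle_ahead_doubles(self):
        assert drip.qpcr_percent_ip(25.0, 24.0) == pytest.approx(10.0)

    def test_behind_by_log2_twenty(self):
        d = np.log2(0.05)  # IP runs behind: recovers 5% of 5% = 0.25%
        assert drip.qpcr_percent_ip(20.0, 20.0 - d) == pytest.approx(0.25)

    def test_efficiency_below_two(self):
        assert drip.qpcr_percent_ip(25.0, 24.0, efficiency=1.5) == pytest.approx(7.5)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            drip.qpcr_percent_ip(25.0, 24.0, efficiency=2.5)
        with pytest.raises(ValueError):
            drip.qpcr_percent_ip(25.0, 24.0, input_fraction=0.0)
        with pytest.raises(ValueError):
            drip.qpcr_percent_ip(float("nan"), 24.0)

    def test_adjust_example_and_invariance(self):
        assert drip.qpcr_adjust(2.0, 50.0) == pytest.approx(4.0)
        # halving IP recovery halves both locus and spike %IP: adjusted stable
        assert drip.qpcr_adjust(1.0, 25.0) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            drip.qpcr_adjust(2.0, 0.0)


class TestCalibrationOnSimulation:
    def test_calibrated_density_linear_in_true_occupancy(self):
        cfg = SimConfig(seed=13, n_genes=50, genome_length=50_000)
        sim = simulate.gen_drip_experiment(cfg)
        inp, ip = sim.spike[("control", "mock")]
        orv = drip.occupancy_ratio(inp, ip)
        tracks = {
            s: drip.calibrate(sim.coverage[("control", "mock", "IP", s)],
                              orv, ip.n_total)
            for s in ("W", "C")
        }
        dens = drip.gene_density_table(tracks, sim.genes)
        truth = sim.truth.query("condition == 'control' and treatment == 'mock'")
        merged = dens.merge(truth, on="gene_id")
        res = stats.linregress(merged["true_template_density"],
                               merged["template_density"])
        assert res.slope > 0
        assert res.rvalue ** 2 > 0.95

    def test_calibrated_signal_depth_invariant_on_simulation(self):
        cfg = SimConfig(seed=13, n_genes=20, genome_length=20_000)
        sim = simulate.gen_drip_experiment(cfg)
        inp, ip = sim.spike[("control", "mock")]
        orv = drip.occupancy_ratio(inp, ip)
        cov = sim.coverage[("control", "mock", "IP", "W")]
        cal = drip.calibrate(cov, orv, ip.n_total)
        # uniform 3x depth: counts, totals and spike counts all scale
        cov3 = StrandedCoverage(
            sample_id=cov.sample_id, condition=cov.condition,
            treatment=cov.treatment, fraction=cov.fraction, genome=cov.genome,
            strand=cov.strand,
            bins=cov.bins.assign(count=cov.bins["count"] * 3),
        )
        ip3 = SpikeInCounts(ip.sample_id, ip.fraction, ip.n_spike * 3, ip.n_total * 3)
        orv3 = drip.occupancy_ratio(inp, ip3)
        cal3 = drip.calibrate(cov3, orv3, ip3.n_total)
        assert np.allclose(cal.bins["count"], cal3.bins["count"])
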