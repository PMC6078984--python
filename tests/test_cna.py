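"""Array QC metrics, QC gate, FGA, arm comparison and gene-level calls."""

import numpy as np
import pytest

from bcpgenomics.cna import (
    ArrayQc, GeneRegion, arm_frequency_comparison, fraction_genome_altered,
    gene_level_call, mapd, median_autocorrelation, qc_gate,
)
from bcpgenomics.io import ProbeSeries, SegmentRecord


def _series(values, chrom="1", sample="S"):
    values = np.asarray(values, dtype=float)
    return ProbeSeries(sample, {chrom: np.arange(1, len(values) + 1)}, {chrom: values})


class TestMapd:
    def test_alternating_series(self):
        assert mapd(_series([0.0, 0.1] * 20)) == pytest.approx(0.1)

    def test_constant_series(self):
        assert mapd(_series([0.3] * 10)) == 0.0

    def test_gaussian_noise_half_normal_median(self):
        """For iid N(0, s^2) probes, adjacent diffs are N(0, 2s^2); the
        median absolute difference is 0.6745 * sqrt(2) * s = 0.954 s."""
        rng = np.random.default_rng(0)
        s = 0.2
        v = rng.normal(0, s, 100000)
        assert mapd(_series(v)) == pytest.approx(0.954 * s, abs=0.01)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.1, 500)
        assert mapd(_series(v)) == pytest.approx(mapd(_series(v + 3.0)), abs=1e-12)

    def test_single_probe_rejected(self):
        with pytest.raises(ValueError):
            mapd(_series([0.1]))


class TestMedianAutocorrelation:
    def test_alternating_perfect_anticorrelation(self):
        assert median_autocorrelation(_series([0.4, -0.4] * 30)) == pytest.approx(-1.0)

    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(2)
        assert median_autocorrelation(_series(rng.normal(size=100000))) == pytest.approx(
            0.0, abs=0.01
        )

    def test_planted_segment_positive(self):
        rng = np.random.default_rng(3)
        signal = np.concatenate([np.zeros(500), np.full(500, 0.8)])
        v = signal + rng.normal(0, 0.2, 1000)
        assert median_autocorrelation(_series(v)) > 0.2

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 0.1, 300)
        assert median_autocorrelation(_series(v)) == pytest.approx(
            median_autocorrelation(_series(v + 5.0)), abs=1e-12
        )

    def test_zero_variance_chromosome_excluded(self):
        ps = ProbeSeries(
            "S",
            {"1": np.arange(1, 101), "2": np.arange(1, 101)},
            {"1": np.zeros(100), "2": np.sin(np.arange(100))},
        )
        # chromosome 1 has zero variance; metric comes from chromosome 2 only
        assert np.isfinite(median_autocorrelation(ps))
        with pytest.raises(ValueError):
            median_autocorrelation(_series([1.0, 1.0, 1.0]))


class TestQcGate:
    def _qc(self, sample, m, a):
        return ArrayQc(sample, m, a)

    def test_mapd_boundary(self):
        gate = qc_gate([self._qc("S", 0.31, 0.1)], {"S": 0.9})
        assert not gate.loc[0, "passed"]
        assert gate.loc[0, "reasons"] == "MAPD"

    def test_ccf_boundary(self):
        gate = qc_gate([self._qc("S", 0.1, 0.1)], {"S": 0.29})
        assert gate.loc[0, "reasons"] == "CCF"

    def test_all_passing(self):
        gate = qc_gate([self._qc("S", 0.30, 0.5)], {"S": 0.30})
        assert gate.loc[0, "passed"]
        assert gate.loc[0, "reasons"] == ""

    def test_reasons_exhaustive(self):
        gate = qc_gate([self._qc("S", 0.5, 0.9)], {"S": 0.1})
        assert gate.loc[0, "reasons"] == "MAPD;autocorrelation;CCF"
        assert not gate.loc[0, "passed"]


class TestFga:
    def test_thirty_percent_altered(self):
        segs = [
            SegmentRecord("S", "1", 1, 300, 10, 0.8),
            SegmentRecord("S", "1", 301, 1000, 10, 0.0),
        ]
        assert fraction_genome_altered(segs) == pytest.approx(0.30)

    def test_all_neutral(self):
        segs = [SegmentRecord("S", "1", 1, 500, 10, 0.1)]
        assert fraction_genome_altered(segs) == 0.0

    def test_split_invariance(self):
        whole = [SegmentRecord("S", "1", 1, 1000, 10, 0.5)]
        split = [SegmentRecord("S", "1", 1, 400, 4, 0.5),
                 SegmentRecord("S", "1", 401, 1000, 6, 0.5)]
        assert fraction_genome_altered(whole) == fraction_genome_altered(split)

    def test_sex_chromosomes_excluded(self):
        segs = [SegmentRecord("S", "1", 1, 100, 10, 0.0),
                SegmentRecord("S", "X", 1, 900, 10, 0.9)]
        assert fraction_genome_altered(segs) == 0.0

    def test_ground_truth_recovery(self, cohort_default):
        for pid in cohort_default.truth.index:
            fga = fraction_genome_altered(cohort_default.segments[pid])
            assert fga == pytest.approx(cohort_default.truth.loc[pid, "fga_true"], abs=1e-9)


class TestArmComparison:
    def test_identical_groups_fdr_one(self):
        from bcpgenomics.genome import load_arms

        segs = {"A": [SegmentRecord("A", "1", 1, 10700, 100, 0.5)],
                "B": [SegmentRecord("B", "1", 1, 10700, 100, 0.5)]}
        groups = {"A": "BCP", "B": "control"}
        out = arm_frequency_comparison(segs, groups, load_arms())
        assert (out["fdr"] == 1.0).all()

    def test_half_covered_arm_not_called(self):
        from bcpgenomics.genome import load_arms

        arms = load_arms()
        arm1p = arms[arms["arm"] == "1p"].iloc[0]
        # exactly 49% of the arm length gained -> below the >50% rule
        span = int(0.49 * (arm1p.end - arm1p.start + 1))
        segs = {"A": [SegmentRecord("A", "1", int(arm1p.start), int(arm1p.start) + span - 1,
                                    10, 0.6)],
                "B": [SegmentRecord("B", "1", int(arm1p.start), int(arm1p.end), 10, 0.0)]}
        out = arm_frequency_comparison(segs, {"A": "BCP", "B": "control"}, arms)
        gain_1p = out[(out["arm"] == "1p") & (out["direction"] == "gain")].iloc[0]
        assert gain_1p["n_bcp"] == 0

    def test_planted_group_difference_detected(self):
        from bcpgenomics.genome import load_arms
        from bcpgenomics.simulate import CohortParams, simulate_cohort

        params = CohortParams(
            n_bcp=100, n_control=100, seed=31,
            arm_events={"1q": ("gain", 0.6, 0.1), "2q": ("gain", 0.2, 0.2),
                        "3p": ("loss", 0.35, 0.35)},
        )
        c = simulate_cohort(params, stages={"clinical", "cna"})
        out = arm_frequency_comparison(c.segments, c.groups(), load_arms())
        row = out[(out["arm"] == "1q") & (out["direction"] == "gain")].iloc[0]
        assert row["freq_bcp"] > row["freq_control"]
        assert row["fdr"] < 0.05


class TestGeneLevelCall:
    REGION = GeneRegion("G", "1", 1001, 2000)

    def test_deep_deletion(self):
        segs = [SegmentRecord("S", "1", 1, 5000, 10, -0.8)]
        assert gene_level_call(segs, self.REGION) == "deleted"

    def test_length_weighted_mean(self):
        # 30% of the gene at -0.8, 70% at 0.0 -> mean -0.24 -> neutral
        segs = [SegmentRecord("S", "1", 1001, 1300, 10, -0.8),
                SegmentRecord("S", "1", 1301, 2000, 10, 0.0)]
        assert gene_level_call(segs, self.REGION) == "neutral"

    def test_gain(self):
        segs = [SegmentRecord("S", "1", 500, 2500, 10, 0.45)]
        assert gene_level_call(segs, self.REGION) == "gained"

    def test_uncovered_gene(self):
        segs = [SegmentRecord("S", "2", 1, 5000, 10, -0.8)]
        with pytest.raises(ValueError, match="not covered"):
            gene_level_call(segs, self.REGION)

    def test_msh2_truth_table_recovery(self):
        from bcpgenomics.simulate import CohortParams, msh2_region, simulate_cohort

        c = simulate_cohort(CohortParams(n_bcp=100, n_control=100, seed=37),
                            stages={"clinical", "cna"})
        region = msh2_region()
        calls = {
            pid: gene_level_call(c.segments[pid], region) == "deleted"
            for pid in c.truth.index
        }
        agree = np.mean([
            calls[pid] == bool(c.truth.loc[pid, "msh2_deleted"]) for pid in c.truth.index
        ])
        assert agree >= 0.95


def test_default_cohort_arrays_pass_qc(cohort_default):
    from bcpgenomics.cna import array_qc

    qcs = [array_qc(p) for p in cohort_default.probes.values()]
    gate = qc_gate(qcs, cohort_default.truth["ccf"].to_dict())
    assert gate["passed"].mean() >= 0.85
    assert (gate["mapd"] < 0.3).mean() >= 0.9
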