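"""Mucin family analysis: serine gains, Monte-Carlo tests, hotspots, MUCsig."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bcpgenomics.io import ExpressionMatrix, MutationRecord
from bcpgenomics.mucins import (
    GeneFamily, carrier_status, hotspot_detect, is_serine_gain,
    mc_known_db_overlap_test, mc_serine_test, mucin_family, mucsig,
    serine_gain_fraction, _family_effects,
)
from bcpgenomics.mutations import SampleCatalog


def _mis(pid, gene, pc, pos=100, chrom="3"):
    return MutationRecord(pid, chrom, pos, "A", "T", gene, "missense", protein_change=pc)


class TestSerineGain:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("GCA", "TCA", True),   # Ala -> Ser
            ("AGT", "AGA", False),  # Ser -> Arg is a loss
            ("TCA", "TCG", False),  # Ser -> Ser synonymous
            ("ACC", "TCC", True),   # Thr -> Ser
            ("TGG", "TCG", True),   # Trp -> Ser
        ],
    )
    def test_genetic_code_cases(self, ref, alt, expected):
        assert is_serine_gain(ref, alt) is expected

    def test_invalid_codons_rejected(self):
        with pytest.raises(ValueError, match="invalid codon"):
            is_serine_gain("GCA", "GXA")
        with pytest.raises(ValueError, match="exactly one"):
            is_serine_gain("GCA", "TTA")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=3),
           st.integers(0, 2), st.sampled_from("ACGT"))
    def test_never_true_when_ref_already_serine(self, codon, pos, alt):
        from Bio.Seq import Seq

        if str(Seq(codon).translate()) != "S" or codon[pos] == alt:
            return
        alt_codon = codon[:pos] + alt + codon[pos + 1 :]
        assert is_serine_gain(codon, alt_codon) is False


class TestSerineGainFraction:
    def test_nine_of_twentytwo(self):
        recs = [_mis(f"P{i}", "MUC2", "p.T10S") for i in range(9)]
        recs += [_mis(f"Q{i}", "MUC2", "p.T10A") for i in range(13)]
        assert serine_gain_fraction(recs) == pytest.approx(9 / 22, abs=1e-4)

    def test_all_serine(self):
        assert serine_gain_fraction([_mis("P", "MUC2", "p.A5S")]) == 1.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="no missense"):
            serine_gain_fraction([MutationRecord("P", "1", 5, "A", "T", "MUC2", "synonymous")])

    def test_unparseable_protein_change_listed(self):
        with pytest.raises(ValueError, match="unparseable"):
            serine_gain_fraction([_mis("P", "MUC2", "garbage")])


class TestMcSerine:
    def _observed_from_pool(self, pool, rng, m, serine=None):
        rows = pool if serine is None else pool[(pool["alt_aa"] == "S") == serine]
        rows = rows.iloc[rng.integers(0, len(rows), size=m)]
        return [
            MutationRecord(f"P{j}", r.chrom, int(r.pos), r.ref, r.alt, r.gene,
                           "missense", protein_change=f"p.{r.ref_aa}{r.protein_pos}{r.alt_aa}")
            for j, r in enumerate(rows.itertuples())
        ]

    @pytest.fixture(scope="class")
    def missense_pool(self, genome):
        eff = _family_effects(mucin_family(), genome)
        return eff[eff["consequence"] == "missense"].reset_index(drop=True)

    def test_zero_observed_fraction_gives_p_one(self, missense_pool):
        rng = np.random.default_rng(1)
        obs = self._observed_from_pool(missense_pool, rng, 25, serine=False)
        res = mc_serine_test(obs, mucin_family(), n_draws=499, seed=3)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_maximal_statistic_attains_floor(self, missense_pool):
        rng = np.random.default_rng(2)
        obs = self._observed_from_pool(missense_pool, rng, 40, serine=True)
        res = mc_serine_test(obs, mucin_family(), n_draws=999, seed=4)
        assert res.observed == 1.0
        assert res.p == pytest.approx(1 / 1000)

    def test_p_reproducible_and_never_zero(self, missense_pool):
        rng = np.random.default_rng(3)
        obs = self._observed_from_pool(missense_pool, rng, 30)
        r1 = mc_serine_test(obs, mucin_family(), n_draws=999, seed=5)
        r2 = mc_serine_test(obs, mucin_family(), n_draws=999, seed=5)
        assert r1.p == r2.p > 0

    def test_null_matched_observed_is_central(self, missense_pool):
        """Observed sets drawn from the null keep p away from both tails."""
        ps = []
        rng = np.random.default_rng(4)
        for i in range(50):
            obs = self._observed_from_pool(missense_pool, rng, 300)
            ps.append(mc_serine_test(obs, mucin_family(), n_draws=999, seed=i).p)
        assert 0.3 <= np.median(ps) <= 0.7

    def test_uniform_null_flag(self, missense_pool):
        rng = np.random.default_rng(5)
        obs = self._observed_from_pool(missense_pool, rng, 30)
        res = mc_serine_test(obs, mucin_family(), n_draws=499, seed=6, null="uniform")
        assert 0 < res.p <= 1


class TestMcKnownDb:
    def test_saturated_known_set(self, genome):
        fam = mucin_family()
        eff = _family_effects(fam, genome)
        known = set(zip(eff["chrom"], eff["pos"].astype(int), eff["alt"]))
        sub = eff.iloc[:20]
        obs = [MutationRecord(f"P{j}", r.chrom, int(r.pos), r.ref, r.alt, r.gene, "missense")
               for j, r in enumerate(sub.itertuples())]
        res = mc_known_db_overlap_test(obs, known, fam, n_draws=499, seed=1)
        assert res.observed == 20
        assert res.p == 1.0

    def test_empty_known_set_p_one(self, genome):
        obs = [MutationRecord("P", "3", 5000, genome.base("3", 5000),
                              "A" if genome.base("3", 5000) != "A" else "C",
                              "MUC17", "missense")]
        res = mc_known_db_overlap_test(obs, set(), mucin_family(), n_draws=499, seed=1)
        assert res.p == 1.0

    def test_expected_overlap_is_central(self, genome):
        fam = mucin_family()
        eff = _family_effects(fam, genome)
        rng = np.random.default_rng(9)
        idx = rng.choice(len(eff), size=int(0.1 * len(eff)), replace=False)
        known = set(zip(eff["chrom"].iloc[idx], eff["pos"].iloc[idx].astype(int),
                        eff["alt"].iloc[idx]))
        ps = []
        for i in range(50):
            rows = eff.iloc[rng.integers(0, len(eff), size=300)]
            obs = [MutationRecord(f"P{j}", r.chrom, int(r.pos), r.ref, r.alt, r.gene,
                                  "missense")
                   for j, r in enumerate(rows.itertuples())]
            ps.append(mc_known_db_overlap_test(obs, known, fam, n_draws=999, seed=i).p)
        assert 0.2 <= np.median(ps) <= 0.8


class TestHotspots:
    def test_two_patients_same_protein_position(self):
        recs = [_mis("P1", "MUC17", "p.T100S"), _mis("P2", "MUC17", "p.T100S")]
        hot = hotspot_detect(recs)
        assert len(hot) == 1
        assert hot.loc[0, "n_patients"] == 2

    def test_same_patient_twice_is_not_a_hotspot(self):
        recs = [_mis("P1", "MUC17", "p.T100S", 100), _mis("P1", "MUC17", "p.T100S", 100)]
        assert len(hotspot_detect(recs)) == 0

    def test_planted_hotspots_recovered(self, cohort_default):
        fam_set = set(mucin_family().members)
        muc = [r for c in cohort_default.catalogs.values() for r in c.records
               if r.gene in fam_set and r.consequence in ("missense", "nonsense")]
        hot = hotspot_detect(muc)
        detected = set(zip(hot["gene"], hot["protein_pos"]))
        assert set(cohort_default.planted_hotspots) <= detected
        assert len(detected) == len(cohort_default.planted_hotspots)


class TestCarrierStatus:
    def _cats(self):
        return {
            "P1": SampleCatalog("P1", [_mis("P1", "MUC4", "p.A5T")]),
            "P2": SampleCatalog("P2", [MutationRecord("P2", "1", 9, "A", "G", "MUC2",
                                                      "synonymous")]),
            "P3": SampleCatalog("P3", [_mis("P3", "MUC17", "p.A5S")]),
            "P4": SampleCatalog("P4", []),
        }

    def test_artifact_exclusion(self):
        fam = mucin_family()
        cs = carrier_status(self._cats(), fam, exclude={"MUC4", "MUC16"})
        assert not cs["P1"]  # only MUC4 mutated
        assert cs["P3"]

    def test_silent_only_is_non_carrier(self):
        assert not carrier_status(self._cats(), mucin_family())["P2"]

    def test_exclusion_monotonicity(self):
        fam = mucin_family()
        cats = self._cats()
        e1 = carrier_status(cats, fam, exclude={"MUC4"})
        e12 = carrier_status(cats, fam, exclude={"MUC4", "MUC17"})
        assert set(e12[e12].index) <= set(e1[e1].index)

    def test_generator_prevalence_recovery(self, cohort_large_mutations):
        c = cohort_large_mutations
        cs = carrier_status(c.catalogs, mucin_family())
        g = c.truth["group"]
        assert cs[g == "BCP"].mean() == pytest.approx(0.457, abs=0.05)
        assert cs[g == "control"].mean() == pytest.approx(0.111, abs=0.05)


class TestMucsig:
    def test_forced_standardisation(self):
        fam = GeneFamily("fam", ("G1", "G2"))
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["G1", "G2"],
            columns=["S1", "S2", "S3"],
        )
        scores = mucsig(ExpressionMatrix(df), fam)
        assert np.allclose(scores.to_numpy(), [-1.0, 0.0, 1.0])
        assert scores.mean() == pytest.approx(0.0, abs=1e-9)
        assert scores.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_rejected(self):
        fam = GeneFamily("fam", ("G1",))
        df = pd.DataFrame([[2.0, 2.0]], index=["G1"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="sd = 0"):
            mucsig(ExpressionMatrix(df), fam)

    def test_no_family_gene_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["OTHER"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="no family gene"):
            mucsig(ExpressionMatrix(df), GeneFamily("fam", ("G1",)))

    def test_planted_upshift_recovered(self):
        from bcpgenomics.simulate import CohortParams, simulate_cohort
        from bcpgenomics.stats import mann_whitney

        c = simulate_cohort(CohortParams(n_bcp=100, n_control=100, seed=77),
                            stages={"expression"})
        scores = mucsig(c.expression, mucin_family())
        g = c.truth["group"]
        bcp, ctl = scores[g == "BCP"], scores[g == "control"]
        assert bcp.mean() > ctl.mean()
        assert mann_whitney(bcp, ctl).p < 0.05


def test_family_validation():
    with pytest.raises(ValueError):
        GeneFamily("empty", ())
    with pytest.raises(ValueError, match="duplicate"):
        GeneFamily("dup", ("MUC2", "MUC2"))
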