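import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genfactor import genio
from genfactor.prs import (
    DEFAULT_THRESHOLDS,
    GenotypePanel,
    SummaryStatRecord,
    clump,
    filter_variants,
    impute_mz_genotypes,
    score_profiles,
    standardize_beta,
    standardize_effects,
)


def record(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", z=1.0, p=None,
           freq=0.3, n=50_000.0, info=1.0, multi=False):
    from scipy.stats import norm
    if p is None:
        p = 2 * norm.sf(abs(z))
    return SummaryStatRecord(vid, chrom, pos, ea, oa, z, p, freq, n, info, multi)


def toy_panel(dosages, ids=None, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    ids = ids or [f"rs{i+1}" for i in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": positions or [1000 * (i + 1) for i in range(m)],
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    samples = [f"S{i+1}" for i in range(dosages.shape[0])]
    return GenotypePanel(sample_ids=samples, variants=variants, dosages=dosages)


class TestStandardizeBeta:
    def test_zero_z_gives_zero(self):
        assert standardize_beta(0.0, 1000, 0.3) == 0.0

    def test_antisymmetric_in_z(self):
        b = standardize_beta(2.5, 10_000, 0.2)
        assert standardize_beta(-2.5, 10_000, 0.2) == pytest.approx(-b)

    def test_worked_value(self):
        # z=5, p=0.5, n=50,000: 5 / sqrt(0.5 * 50,025)
        assert standardize_beta(5.0, 50_000, 0.5) == pytest.approx(
            5.0 / math.sqrt(0.5 * 50_025.0), rel=1e-12
        )
        assert standardize_beta(5.0, 50_000, 0.5) == pytest.approx(0.031615, abs=5e-7)

    @pytest.mark.parametrize("freq,n", [(0.0, 100), (1.0, 100), (0.3, 0)])
    def test_domain_errors_name_variant(self, freq, n):
        with pytest.raises(ValueError, match="rs99"):
            standardize_beta(1.0, n, freq, variant_id="rs99")

    @given(z=st.floats(-30, 30), n=st.floats(10, 1e6),
           p=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_sign_matches_z(self, z, n, p):
        assert np.sign(standardize_beta(z, n, p)) == np.sign(z)


class TestFilterVariants:
    def test_empty_input(self):
        kept, tally = filter_variants([])
        assert kept == [] and sum(tally.values()) == 0

    def test_high_frequency_is_low_maf(self):
        rec = record(freq=0.97)
        kept, tally = filter_variants([rec])
        assert kept == [] and tally["maf"] == 1

    def test_toy_six_record_battery(self):
        recs = [
            record("v1", ea="AC", oa="A"),          # indel
            record("v2", ea="A", oa="T"),           # strand-ambiguous
            record("v3", info=0.5),                 # low INFO
            record("v4"), record("v5"), record("v6"),
        ]
        kept, tally = filter_variants(recs)
        assert [r.variant_id for r in kept] == ["v4", "v5", "v6"]
        assert tally == {"indel": 1, "multiallelic": 0, "ambiguous": 1,
                         "maf": 0, "info": 1}

    def test_order_preserved(self):
        recs = [record(f"v{i}", freq=0.3) for i in range(5)]
        kept, _ = filter_variants(recs)
        assert [r.variant_id for r in kept] == [r.variant_id for r in recs]


def brute_force_clump(records, ld, r2_max, window_kb):
    """Literal restatement of the clumping rule, kept independent of the
    implementation: repeatedly scan for the best remaining variant."""
    remaining = {r.variant_id: r for r in records}
    out = []
    while remaining:
        best = min(
            remaining.values(),
            key=lambda r: (r.p_value, str(r.chromosome), r.position, r.variant_id),
        )
        out.append(best.variant_id)
        del remaining[best.variant_id]
        for other in list(remaining.values()):
            if str(other.chromosome) != str(best.chromosome):
                continue
            if abs(other.position - best.position) > window_kb * 1000:
                continue
            key = (best.variant_id, other.variant_id)
            r2 = ld.get(key, ld.get(key[::-1], 0.0))
            if r2 > r2_max:
                del remaining[other.variant_id]
    return out


class TestClump:
    def test_single_variant(self):
        rec = record("solo")
        idx, rep = clump([rec], {}, 0.1, 1000)
        assert idx == ["solo"] and rep == {"solo": []}

    def test_three_variant_example(self):
        a = record("A", pos=1_000_000, z=5.73)   # p ~ 1e-8
        b = record("B", pos=1_100_000, z=3.89)   # p ~ 1e-4
        c = record("C", pos=2_500_000, z=3.29)   # p ~ 1e-3
        ld = {("A", "B"): 0.25, ("A", "C"): 0.0, ("B", "C"): 0.0}
        idx, rep = clump([a, b, c], ld, r2_max=0.1, window_kb=1000)
        assert idx == ["A", "C"]
        assert rep["A"] == ["B"]

    def test_matches_brute_force_on_small_instances(self):
        """Greedy output equals an independent reference on all instances
        with up to 6 variants under varied LD and positions."""
        rng = np.random.default_rng(5)
        for trial in range(60):
            m = int(rng.integers(1, 7))
            recs = []
            for i in range(m):
                recs.append(
                    record(
                        f"v{i}",
                        chrom=str(rng.integers(1, 3)),
                        pos=int(rng.integers(1, 3_000_000)),
                        z=float(rng.normal() * 3),
                        freq=float(rng.uniform(0.05, 0.5)),
                    )
                )
            ld = {}
            for i in range(m):
                for j in range(i + 1, m):
                    ld[(f"v{i}", f"v{j}")] = float(rng.uniform(0, 1))
            got, _ = clump(recs, ld, r2_max=0.1, window_kb=1000)
            want = brute_force_clump(recs, ld, r2_max=0.1, window_kb=1000)
            assert got == want

    def test_missing_ld_variant_is_reported(self):
        panel = toy_panel(np.zeros((4, 1)), ids=["known"])
        with pytest.raises(KeyError, match="stranger"):
            clump([record("stranger")], panel, 0.1, 1000)


class TestScoreProfiles:
    def test_zero_betas_zero_scores(self):
        panel = toy_panel([[0, 1], [2, 1]])
        ss = [record("rs1", pos=1000), record("rs2", pos=2000)]
        eff = pd.DataFrame({"variant_id": ["rs1", "rs2"], "beta_std": [0.0, 0.0]})
        res = score_profiles(panel, eff, ss, thresholds=[1.0])
        assert np.allclose(res.scores(1.0, standardized=False), 0.0)

    def test_hand_arithmetic(self):
        panel = toy_panel([[2, 1]])
        ss = [record("rs1", pos=1000), record("rs2", pos=2000)]
        eff = pd.DataFrame({"variant_id": ["rs1", "rs2"], "beta_std": [0.1, -0.2]})
        res = score_profiles(panel, eff, ss, thresholds=[1.0])
        # (2*0.1 + 1*(-0.2)) / (2*2) = 0
        assert res.scores(1.0, standardized=False).iloc[0] == pytest.approx(0.0)

    def test_missing_genotype_drops_from_denominator(self):
        panel = toy_panel([[2.0, np.nan], [2.0, 2.0]])
        ss = [record("rs1", pos=1000), record("rs2", pos=2000)]
        eff = pd.DataFrame({"variant_id": ["rs1", "rs2"], "beta_std": [0.1, 0.3]})
        res = score_profiles(panel, eff, ss, thresholds=[1.0])
        raw = res.scores(1.0, standardized=False)
        assert raw["S1"] == pytest.approx(0.2 / 2.0)       # one variant only
        assert raw["S2"] == pytest.approx((0.2 + 0.6) / 4.0)
        tab = res.table.set_index("sample_id")
        assert tab.loc["S1", "n_variants"] == 1
        assert tab.loc["S2", "n_variants"] == 2

    def test_no_variant_under_threshold_is_nan_not_zero(self):
        panel = toy_panel([[2.0]])
        ss = [record("rs1", z=0.5)]  # p ~ 0.6
        eff = pd.DataFrame({"variant_id": ["rs1"], "beta_std": [0.1]})
        res = score_profiles(panel, eff, ss, thresholds=[1e-5, 1.0])
        assert np.isnan(res.scores(1e-5, standardized=False).iloc[0])
        assert res.included[1e-5] == []

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(2)
        panel = toy_panel(rng.integers(0, 3, size=(6, 4)).astype(float))
        ss = [record(f"rs{i+1}", pos=1000 * (i + 1), z=rng.normal())
              for i in range(4)]
        eff = standardize_effects(ss)
        res1 = score_profiles(panel, eff, ss, thresholds=[1.0])
        eff3 = eff.assign(beta_std=eff["beta_std"] * 3.0)
        res3 = score_profiles(panel, eff3, ss, thresholds=[1.0])
        assert np.allclose(
            res3.scores(1.0, standardized=False),
            3.0 * res1.scores(1.0, standardized=False),
        )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        panel = toy_panel(rng.integers(0, 3, size=(5, 8)).astype(float))
        ss = [record(f"rs{i+1}", pos=1000 * (i + 1), z=float(rng.normal() * 2))
              for i in range(8)]
        eff = standardize_effects(ss)
        res = score_profiles(panel, eff, ss, thresholds=DEFAULT_THRESHOLDS)
        thr = sorted(DEFAULT_THRESHOLDS)
        for t1, t2 in zip(thr, thr[1:]):
            assert set(res.included[t1]) <= set(res.included[t2])

    def test_standardized_scores_have_unit_moments(self):
        rng = np.random.default_rng(4)
        panel = toy_panel(rng.integers(0, 3, size=(50, 3)).astype(float))
        ss = [record(f"rs{i+1}", pos=1000 * (i + 1), z=2.0) for i in range(3)]
        eff = standardize_effects(ss)
        res = score_profiles(panel, eff, ss, thresholds=[1.0])
        z = res.scores(1.0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-9)


class TestImputeMZ:
    def test_empty_pairs_is_identity(self):
        panel = toy_panel([[0, 1], [2, 1]])
        assert impute_mz_genotypes(panel, {}) is panel

    def test_copy_and_scoring_identity(self):
        rng = np.random.default_rng(1)
        panel = toy_panel(rng.integers(0, 3, size=(3, 5)).astype(float))
        out = impute_mz_genotypes(panel, {"S1_twin": "S1"})
        i_new = out.sample_index("S1_twin")
        i_src = out.sample_index("S1")
        assert np.array_equal(out.dosages[i_new], out.dosages[i_src])
        assert out.imputed_from["S1_twin"] == "S1"
        ss = [record(f"rs{i+1}", pos=1000 * (i + 1), z=2.0) for i in range(5)]
        eff = standardize_effects(ss)
        res = score_profiles(out, eff, ss, thresholds=[1.0])
        raw = res.scores(1.0, standardized=False)
        assert raw["S1_twin"] == pytest.approx(raw["S1"])

    def test_absent_cotwin_errors(self):
        panel = toy_panel([[0.0]])
        with pytest.raises(KeyError, match="ghost"):
            impute_mz_genotypes(panel, {"new": "ghost"})


class TestRoundTrips:
    def test_sumstats_tsv(self, tmp_path):
        recs = [record(f"v{i}", z=float(i) - 1.5, freq=0.1 + 0.05 * i)
                for i in range(5)]
        path = tmp_path / "ss.tsv"
        genio.write_sumstats(recs, path)
        back = genio.read_sumstats(path)
        assert len(back) == len(recs)
        for a, b in zip(back, recs):
            assert a.variant_id == b.variant_id
            assert a.position == b.position
            assert (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele)
            assert a.z == pytest.approx(b.z)
            assert a.p_value == pytest.approx(b.p_value)
            assert a.allele_freq == pytest.approx(b.allele_freq)
            a.validate()

    def test_traw(self, tmp_path):
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(4, 3)).astype(float)
        dos[1, 2] = np.nan
        panel = toy_panel(dos)
        path = tmp_path / "geno.traw"
        genio.write_traw(panel, path)
        back = genio.read_traw(path)
        assert back.sample_ids == panel.sample_ids
        assert np.allclose(back.dosages, panel.dosages, equal_nan=True)
        pd.testing.assert_frame_equal(back.variants, panel.variants)

    def test_vcf(self, tmp_path):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(3, 4)).astype(float)
        dos[0, 1] = np.nan
        panel = toy_panel(dos)
        path = tmp_path / "geno.vcf"
        genio.write_vcf(panel, path)
        back = genio.read_vcf(path)
        assert back.sample_ids == panel.sample_ids
        order = [back.variant_index(v) for v in panel.variants["variant_id"]]
        assert np.allclose(back.dosages[:, order], panel.dosages, equal_nan=True)
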