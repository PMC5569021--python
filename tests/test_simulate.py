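"""Synthetic-data generators: expectations, quotas, determinism, truth."""

import numpy as np
import pandas as pd
import pytest

from chorline.cnv import GenomicInterval
from chorline.simulate import (
    CnvEvent,
    CnvScenario,
    CountScenario,
    VariantScenario,
    chor_in_1_scenario,
    gen_counts,
    gen_coverage,
    gen_ct_table,
    gen_growth,
    gen_variant_sets,
    make_panel,
)
from chorline.variants import SYNONYMOUS


class TestGenCoverage:
    def test_noiseless_diploid_baseline_is_exact(self):
        scenario = CnvScenario(noise_model="none", base_depth=100.0)
        track = gen_coverage(scenario, make_panel(spacing=10_000_000))
        assert np.all(track.depths == 100.0)

    def test_biallelic_deletion_has_zero_expected_depth(self):
        scenario = chor_in_1_scenario(noise_model="none")
        panel = make_panel(spacing=1_000_000)
        track = gen_coverage(scenario, panel)
        inside = [i for i, iv in enumerate(panel)
                  if iv.chrom == "chr9" and 19_900_000 <= iv.midpoint < 25_600_000]
        assert len(inside) >= 5
        assert all(track.depths[i] == 0.0 for i in inside)

    def test_event_intervals_scale_with_copy_number(self):
        scenario = chor_in_1_scenario(noise_model="none")
        panel = make_panel(spacing=1_000_000)
        track = gen_coverage(scenario, panel)
        for i, iv in enumerate(panel):
            cn = scenario.copy_number_at(iv.chrom, iv.midpoint)
            assert track.depths[i] == pytest.approx(100.0 * cn / 2)

    def test_poisson_mean_depth_close_to_base_depth(self):
        panel = [GenomicInterval("chr1", s, s + 500) for s in range(0, 500_000, 500)]
        scenario = CnvScenario(noise_model="poisson", base_depth=100.0, seed=7)
        track = gen_coverage(scenario, panel)
        assert len(track) == 1000
        assert abs(track.depths.mean() - 100.0) < 1.0

    def test_contamination_floor_lifts_homozygous_deletions(self):
        scenario = chor_in_1_scenario(noise_model="none", contamination=0.1)
        panel = make_panel(spacing=1_000_000)
        track = gen_coverage(scenario, panel)
        inside = [i for i, iv in enumerate(panel)
                  if iv.chrom == "chr9" and 19_900_000 <= iv.midpoint < 25_600_000]
        assert all(track.depths[i] == pytest.approx(10.0) for i in inside)

    def test_identical_seed_gives_identical_output(self):
        panel = make_panel(spacing=5_000_000)
        a = gen_coverage(chor_in_1_scenario(seed=3), panel)
        b = gen_coverage(chor_in_1_scenario(seed=3), panel)
        c = gen_coverage(chor_in_1_scenario(seed=4), panel)
        assert np.array_equal(a.depths, b.depths)
        assert not np.array_equal(a.depths, c.depths)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            CnvScenario(events=[CnvEvent("chr1", 0, 1000, 1),
                                CnvEvent("chr1", 500, 2000, 3)])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty panel"):
            gen_coverage(CnvScenario(), [])

    def test_event_beyond_chromosome_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            CnvScenario(events=[CnvEvent("chr21", 0, 999_999_999, 1)])

    def test_negative_binomial_is_overdispersed(self):
        panel = [GenomicInterval("chr1", s, s + 500) for s in range(0, 2_000_000, 500)]
        pois = gen_coverage(CnvScenario(noise_model="poisson", seed=1), panel)
        nb = gen_coverage(CnvScenario(noise_model="negative_binomial",
                                      dispersion=0.05, seed=1), panel)
        assert nb.depths.var() > 2 * pois.depths.var()


class TestGenVariantSets:
    def test_empty_scenario_gives_empty_sets(self):
        cell, tumor, normal, truth = gen_variant_sets(
            VariantScenario(n_germline=0, n_tumor_only=0))
        assert cell == tumor == normal == [] and truth == {}

    def test_structure_of_membership(self):
        cell, tumor, normal, truth = gen_variant_sets(
            VariantScenario(n_germline=30, n_tumor_only=4, n_normal_only=2, seed=1))
        kc = {r.key() for r in cell}
        kt = {r.key() for r in tumor}
        kn = {r.key() for r in normal}
        for key, info in truth.items():
            if info["label"] == "germline":
                assert key in kc and key in kt and key in kn
            elif info["label"] == "tumor_only":
                assert key in kc and key in kt and key not in kn
            else:
                assert key not in kc and key not in kt and key in kn

    def test_synonymous_quota_is_exact(self):
        cell, *_ = gen_variant_sets(VariantScenario(
            n_germline=100, n_tumor_only=0, fraction_synonymous=0.2, seed=5))
        assert sum(r.effect == SYNONYMOUS for r in cell) == 20

    def test_common_maf_quota_is_exact(self):
        cell, *_ = gen_variant_sets(VariantScenario(
            n_germline=50, n_tumor_only=0, fraction_common=0.1, seed=5))
        assert sum(r.maf is not None and r.maf > 0.02 for r in cell) == 5

    def test_tumor_only_genes_labeled_as_requested(self):
        *_, truth = gen_variant_sets(VariantScenario(n_germline=10, seed=2))
        genes = sorted(v["gene"] for v in truth.values() if v["label"] == "tumor_only")
        assert genes == ["KEL", "MUC1", "SART3", "TECTA"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            VariantScenario(n_germline=-1)

    def test_deterministic(self):
        a = gen_variant_sets(VariantScenario(seed=9))
        b = gen_variant_sets(VariantScenario(seed=9))
        assert [r.key() for r in a[0]] == [r.key() for r in b[0]]
        assert [(r.dp, r.adv) for r in a[0]] == [(r.dp, r.adv) for r in b[0]]


class TestGenCounts:
    def test_poisson_limit_means_recovered(self):
        scenario = CountScenario(n_genes=500, dispersion=0.0, seed=8,
                                 sample_ids=tuple(f"s{i}" for i in range(5)))
        counts, truth = gen_counts(scenario)
        means = truth["gene_means"]
        se = np.sqrt(means / counts.shape[1])
        z = (counts.mean(axis=1) - means) / se
        assert (np.abs(z) < 3).mean() > 0.99
        assert abs(z.mean()) < 0.2

    def test_all_zero_means_give_zero_matrix(self):
        scenario = CountScenario(n_genes=4, sample_ids=("only",),
                                 gene_means=np.zeros(4), seed=0)
        counts, _ = gen_counts(scenario)
        assert (counts.values == 0).all()

    def test_shift_applies_to_named_gene_and_sample(self):
        scenario = CountScenario(
            n_genes=50, sample_ids=("Chor-IN-1", "a", "b", "c"),
            gene_means=np.full(50, 1000.0), dispersion=0.0,
            differential=[("ULK4", "Chor-IN-1", 3.0)], seed=4)
        counts, _ = gen_counts(scenario)
        assert counts.loc["ULK4", "Chor-IN-1"] > 4 * counts.loc["ULK4", "a"]

    def test_counts_are_nonnegative_integers(self):
        counts, _ = gen_counts(CountScenario(n_genes=30, seed=2))
        assert (counts.values >= 0).all()
        assert np.issubdtype(counts.values.dtype, np.integer)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            CountScenario(dispersion=-0.1)

    def test_deterministic(self):
        a, _ = gen_counts(CountScenario(n_genes=40, seed=6))
        b, _ = gen_counts(CountScenario(n_genes=40, seed=6))
        assert a.equals(b)


class TestGrowthAndCt:
    def test_noiseless_growth_is_exact_exponential(self):
        t, n = gen_growth(1000, 168.0, [0.0, 84.0, 168.0], cv=0.0)
        assert np.allclose(n, [1000, 1000 * 2 ** 0.5, 2000])

    def test_noise_has_requested_scale(self):
        _, n = gen_growth(1000, 168.0, np.arange(200) * 1.0, cv=0.05, seed=2)
        expected = 1000 * 2 ** (np.arange(200) / 168.0)
        rel = n / expected
        assert 0.03 < rel.std() < 0.08

    def test_ct_table_duplicates_and_structure(self):
        expr = pd.DataFrame({"GUSB": [1.0], "PPIA": [1.0], "18S": [1.0],
                             "TGT": [4.0]}, index=["U-CH1"])
        table = gen_ct_table(expr)
        assert len(table) == 8  # 4 genes x duplicate reactions
        tgt = table[table["gene"] == "TGT"]["ct"].iloc[0]
        ref = table[table["gene"] == "GUSB"]["ct"].iloc[0]
        assert ref - tgt == pytest.approx(2.0)  # 4-fold expression = 2 cycles

    def test_ct_rejects_nonpositive_expression(self):
        expr = pd.DataFrame({"GUSB": [0.0], "PPIA": [1.0], "18S": [1.0]},
                            index=["s"])
        with pytest.raises(ValueError):
            gen_ct_table(expr)
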