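"""Generator properties: sum condition, binomial VAF model, artifact labels."""

import numpy as np
import pandas as pd
import pytest

from ctlong import simdata
from ctlong.simdata import (SimConfig, inject_artifacts, inject_kataegis,
                            simulate_clone_tree, simulate_cohort,
                            simulate_fragments, simulate_reads,
                            simulate_spectrum, toy_signature_matrix)


class TestCloneTree:
    def test_single_clone(self):
        cfg = SimConfig(seed=1, n_clones=1, n_timepoints=3,
                        tumour_fraction_per_timepoint=(0.2, 0.1, 0.1),
                        plasma_days=(1, 2, 3))
        clones, truth = simulate_clone_tree(cfg)
        assert len(clones) == 1 and clones[0].parent_id is None
        assert truth["prevalence"].shape == (1, 3)

    def test_determinism(self):
        cfg = SimConfig(seed=11)
        _, t1 = simulate_clone_tree(cfg)
        _, t2 = simulate_clone_tree(cfg)
        pd.testing.assert_frame_equal(t1["mutations"], t2["mutations"])
        pd.testing.assert_frame_equal(t1["prevalence"], t2["prevalence"])
        assert t1["parents"] == t2["parents"]

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_condition_holds_everywhere(self, seed):
        """Brute-force walk: every parent's prevalence >= sum of children's."""
        cfg = SimConfig(seed=seed, n_clones=7, muts_per_clone=2)
        clones, truth = simulate_clone_tree(cfg)
        prev = truth["prevalence"].to_numpy()
        parents = truth["parents"]
        for j in range(prev.shape[1]):
            for node in range(len(clones)):
                child_sum = sum(prev[c, j] for c in range(len(clones))
                                if parents[c] == node)
                assert prev[node, j] >= child_sum - 1e-12
            assert prev[0, j] <= 1.0

    def test_zero_mutations_rejected(self):
        with pytest.raises(ValueError, match="muts_per_clone"):
            SimConfig(muts_per_clone=0)


class TestReads:
    def test_expected_alt_count_matches_binomial_mean(self):
        """t=0.5, P=0.4, depth 1000: mean alt count ~ 100 within 3 SE."""
        rng = np.random.default_rng(0)
        n_rep, depth, v = 500, 1000, 0.5 * 0.5 * 0.4
        alts = rng.binomial(depth, v, size=n_rep)  # the generator's model
        # and through the generator itself: one clone, fixed prevalence
        cfg = SimConfig(seed=3, n_clones=1, muts_per_clone=1, n_timepoints=1,
                        tumour_fraction_per_timepoint=(0.5,), plasma_days=(1,),
                        include_tumour=False)
        sim_alts = []
        rng2 = np.random.default_rng(3)
        clones, _ = simulate_clone_tree(cfg, rng2)
        clones[0].prevalence[:] = 0.4
        for _ in range(n_rep):
            _, tables = simulate_reads(clones, cfg, rng2)
            rec = tables["PT01_P1"][0]
            sim_alts.append(rec.alt_count)
        se = np.sqrt(depth * v * (1 - v) / n_rep)
        assert abs(np.mean(sim_alts) - depth * v) < 3 * se
        assert abs(np.mean(alts) - depth * v) < 3 * se

    def test_cleared_tumour_gives_zero_alt(self):
        cfg = SimConfig(seed=4, n_timepoints=2,
                        tumour_fraction_per_timepoint=(0.0, 0.0),
                        plasma_days=(1, 2), include_tumour=False)
        clones, _ = simulate_clone_tree(cfg)
        _, tables = simulate_reads(clones, cfg, np.random.default_rng(4))
        for sid in ("PT01_P1", "PT01_P2"):
            assert all(r.alt_count == 0 for r in tables[sid])

    def test_germline_has_no_alt_at_somatic_loci(self):
        cfg = SimConfig(seed=5)
        clones, _ = simulate_clone_tree(cfg)
        _, tables = simulate_reads(clones, cfg, np.random.default_rng(5))
        assert all(r.alt_count == 0 for r in tables["PT01_GL"])

    def test_fixed_seed_identical_tables(self):
        cfg = SimConfig(seed=6)
        out = []
        for _ in range(2):
            clones, _ = simulate_clone_tree(cfg)
            _, tables = simulate_reads(clones, cfg, np.random.default_rng(6))
            out.append([(r.key, r.ref_fwd, r.ref_rev, r.alt_fwd, r.alt_rev,
                         r.mean_alt_bq) for recs in tables.values() for r in recs])
        assert out[0] == out[1]


class TestArtifacts:
    def _patient(self, seed=7, **kw):
        cfg = SimConfig(seed=seed, **kw)
        rng = np.random.default_rng(seed)
        clones, _ = simulate_clone_tree(cfg, rng)
        manifest, tables = simulate_reads(clones, cfg, rng)
        return cfg, rng, manifest, tables

    def test_zero_rates_leave_tables_unchanged(self):
        cfg, rng, manifest, tables = self._patient(
            germline_leak_rate=0, cp_shared_rate=0, strand_bias_rate=0,
            blacklist_rate=0, multiallelic_rate=0, dbsnp_only_rate=0,
            low_bq_rate=0, nonexonic_rate=0)
        before = {sid: len(recs) for sid, recs in tables.items()}
        truth = inject_artifacts(tables, manifest, cfg, rng,
                                 simdata.simulate_blacklist(rng))
        assert truth.empty
        assert {sid: len(recs) for sid, recs in tables.items()} == before

    def test_rate_above_one_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            SimConfig(strand_bias_rate=1.5)

    def test_artifact_construction(self):
        cfg, rng, manifest, tables = self._patient()
        truth = inject_artifacts(tables, manifest, cfg, rng,
                                 simdata.simulate_blacklist(rng))
        by_key = {}
        for recs in tables.values():
            for r in recs:
                by_key.setdefault((r.chrom, r.pos, r.ref, r.alt), []).append(r)
        for _, row in truth.iterrows():
            recs = by_key[(row.chrom, row.pos, row.ref, row.alt)]
            if row.artifact_class == "strand_bias":
                plasma = [r for r in recs if "_P" in r.sample_id
                          and not r.sample_id.endswith("_T")]
                for r in plasma:
                    assert min(r.alt_fwd, r.alt_rev) == 0 and r.alt_count > 0
            elif row.artifact_class == "germline_leak":
                germ = [r for r in recs if r.sample_id.endswith("_GL")]
                assert germ and all(g.alt_count >= 1 and g.depth >= 20
                                    for g in germ)
            elif row.artifact_class == "low_bq":
                plasma = [r for r in recs if "_P" in r.sample_id]
                assert all(r.mean_alt_bq < 25 for r in plasma)


class TestKataegisInjection:
    def _tables(self, seed, **kw):
        cfg = SimConfig(seed=seed, **kw)
        rng = np.random.default_rng(seed)
        clones, _ = simulate_clone_tree(cfg, rng)
        manifest, tables = simulate_reads(clones, cfg, rng)
        return cfg, rng, manifest, tables

    def test_injected_cluster_meets_definition(self):
        cfg, rng, manifest, tables = self._tables(
            8, kataegis_cluster_size=6, kataegis_spacing_max=1000)
        truth = inject_kataegis(tables, manifest, cfg, rng)
        assert len(truth) == 1
        assert bool(truth.iloc[0].meets_definition)
        assert truth.iloc[0].n_mutations >= 6 and truth.iloc[0].mean_imd <= 1000

    def test_subthreshold_cluster_labelled(self):
        cfg, rng, manifest, tables = self._tables(9, kataegis_cluster_size=5)
        truth = inject_kataegis(tables, manifest, cfg, rng)
        assert not bool(truth.iloc[0].meets_definition)

    def test_no_clusters(self):
        cfg, rng, manifest, tables = self._tables(10, kataegis_clusters=0)
        truth = inject_kataegis(tables, manifest, cfg, rng)
        assert truth.empty


class TestSpectrum:
    def test_one_hot_recovers_column(self, toy_matrix):
        """Degenerate mixture: empirical spectrum within multinomial L1 error."""
        n = 10_000
        w = np.zeros(10)
        w[3] = 1.0
        counts = simulate_spectrum(toy_matrix, w, n, np.random.default_rng(0))
        emp = counts / counts.sum()
        col = toy_matrix.iloc[:, 3].to_numpy()
        # E|emp_c - p_c| <= sqrt(p_c(1-p_c)/n); bound total L1 at 3x its mean
        l1_bound = 3 * np.sqrt(col * (1 - col) / n).sum()
        assert np.abs(emp - col).sum() < l1_bound

    def test_zero_mutations(self, toy_matrix):
        counts = simulate_spectrum(toy_matrix, np.full(10, 0.1), 0,
                                   np.random.default_rng(0))
        assert counts.sum() == 0

    def test_mixture_expectation_closed_form(self, toy_matrix):
        m2 = toy_matrix.iloc[:, :2]
        w = np.array([0.7, 0.3])
        n = 200_000
        counts = simulate_spectrum(m2, w, n, np.random.default_rng(1))
        expected = (0.7 * m2.iloc[:, 0] + 0.3 * m2.iloc[:, 1]).to_numpy()
        l1_bound = 3 * np.sqrt(expected * (1 - expected) / n).sum()
        assert np.abs(counts / n - expected).sum() < l1_bound

    def test_wrong_exposure_length(self, toy_matrix):
        with pytest.raises(ValueError, match="length"):
            simulate_spectrum(toy_matrix, [0.5, 0.5], 10, np.random.default_rng(0))


class TestFragments:
    def test_modal_size_167(self):
        """Resolving a 1 bp mode on a 10 bp-wide peak needs ~4e7 fragments:
        the count gap between 167 and its neighbours is ~1.7e-4 per fragment,
        so smaller samples leave the argmax to noise."""
        cfg = SimConfig(seed=12)
        lengths = simulate_fragments(cfg, np.random.default_rng(12), n=40_000_000)
        assert np.argmax(np.bincount(lengths)) == 167

    def test_single_fragment_at_least_50(self):
        cfg = SimConfig(seed=13)
        lengths = simulate_fragments(cfg, np.random.default_rng(13), n=1)
        assert lengths.shape == (1,) and lengths[0] >= 50

    def test_pure_dinucleosome_mode(self):
        # the dinucleosome peak is twice as wide (sd 20), so the empirical
        # argmax is only resolvable to a small neighbourhood of 2*167
        cfg = SimConfig(seed=14, dinucleosome_weight=1.0)
        lengths = simulate_fragments(cfg, np.random.default_rng(14), n=1_000_000)
        assert abs(np.argmax(np.bincount(lengths)) - 334) <= 5

    def test_invalid_weight(self):
        cfg = SimConfig(seed=15)
        cfg.dinucleosome_weight = 1.5
        with pytest.raises(ValueError, match="weight"):
            simulate_fragments(cfg, np.random.default_rng(0), n=10)


class TestCohort:
    def test_cp_loci_shared_across_cp_samples(self):
        cohort = simulate_cohort({"PT01": SimConfig(seed=16)}, seed=16)
        keys = [{r.key for r in recs} for recs in cohort.cp_tables.values()]
        assert len(keys) == 2 and keys[0] == keys[1]

    def test_write_cohort_round_trips(self, tmp_path):
        from ctlong.core_io import read_manifest, read_variant_table
        cohort = simulate_cohort({"PT01": SimConfig(seed=17, n_timepoints=3,
                                                    plasma_days=(1, 2, 3))},
                                 seed=17)
        simdata.write_cohort(cohort, tmp_path)
        metas = read_manifest(tmp_path / "manifest.tsv")
        assert len(metas) == len(cohort.manifest)
        recs = read_variant_table(tmp_path / "variants" / "PT01_P1.tsv")
        assert len(recs) == len(cohort.tables["PT01_P1"])
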