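"""The synthetic-data generator: process laws, determinism, cross-consistency."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from famtrait.features import read_membership, read_orthogroup_counts
from famtrait.growth import eauc, phenotype_table, read_plate_table, read_well_metadata
from famtrait.phylo import bm_covariance, read_newick
from famtrait.simulate import (
    SimConfig,
    _branch_transition,
    _stream,
    assign_trait,
    emit_growth_curves,
    evolve_family_counts,
    make_dataset,
    simulate_tree,
)
from famtrait.traits import classify_tails


class TestSimulateTree:
    def test_tip_count_and_labels(self):
        tree = simulate_tree(3, seed=0)
        assert len(tree.tips) == 3
        assert all(t.startswith("sp") for t in tree.tips)

    def test_same_seed_same_newick(self):
        assert simulate_tree(10, seed=4).as_newick() == \
            simulate_tree(10, seed=4).as_newick()

    def test_ultrametric_unit_depth(self):
        tree = simulate_tree(20, seed=1)
        V, _ = bm_covariance(tree)
        np.testing.assert_allclose(np.diag(V), 1.0, atol=1e-9)


class TestBranchTransition:
    def test_frozen_process_copies_parent(self, rng):
        n = rng.integers(0, 5, 100)
        out = _branch_transition(n, 0.7, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out, n)

    def test_pure_death_drives_counts_to_zero(self, rng):
        n = np.full(500, 3)
        out = _branch_transition(n, 50.0, 0.0, 5.0, rng)
        assert out.sum() == 0

    def test_critical_process_preserves_the_mean(self, rng):
        # E[N_t] = N_0 for a critical (dup == loss) linear birth-death
        n0 = 3
        out = _branch_transition(np.full(4000, n0), 0.8, 0.6, 0.6, rng)
        se = out.std() / np.sqrt(len(out))
        assert abs(out.mean() - n0) < 3 * se

    def test_supercritical_mean_growth_law(self, rng):
        # E[N_t] = N_0 * exp((dup - loss) * t)
        n0, lam, mu, t = 2, 1.0, 0.4, 0.5
        out = _branch_transition(np.full(6000, n0), t, lam, mu, rng)
        expected = n0 * np.exp((lam - mu) * t)
        se = out.std() / np.sqrt(len(out))
        assert abs(out.mean() - expected) < 3 * se


class TestEvolveFamilyCounts:
    def test_shapes_and_causal_choice(self, small_config):
        tree = simulate_tree(small_config.n_species, small_config.seed)
        counts, causal = evolve_family_counts(tree, small_config)
        assert counts.shape == (60, 150)
        assert len(causal) == 5
        assert (counts.to_numpy() >= 0).all()
        assert set(causal) <= set(counts.columns)

    def test_sparse_for_small_root_counts(self, small_dataset):
        frac_zero = (small_dataset.counts.to_numpy() == 0).mean()
        assert frac_zero > 0.3  # zero-inflated like real orthogroup matrices


class TestAssignTrait:
    def make(self, config):
        tree = simulate_tree(config.n_species, config.seed)
        counts, causal = evolve_family_counts(tree, config)
        return tree, counts, causal

    def test_null_model_gives_constant_half(self):
        cfg = SimConfig(n_species=20, n_families=30, seed=3,
                        causal_weights=(0.0,) * 5,
                        sigma_phylo=0.0, sigma_iid=0.0)
        tree, counts, causal = self.make(cfg)
        truth = assign_trait(counts, tree, cfg, causal)
        np.testing.assert_allclose(truth.resistance, 0.5, atol=1e-12)

    def test_single_causal_family_monotone(self):
        cfg = SimConfig(n_species=25, n_families=30, seed=5, n_causal=1,
                        causal_weights=(1.0,), sigma_phylo=0.0, sigma_iid=0.0)
        tree, counts, causal = self.make(cfg)
        truth = assign_trait(counts, tree, cfg, causal)
        df = pd.DataFrame({"count": counts[causal[0]],
                           "r": truth.resistance})
        grouped = df.groupby("count")["r"].mean()
        assert grouped.is_monotonic_increasing

    def test_doubling_weights_quadruples_liability_variance(self):
        base = SimConfig(n_species=30, n_families=40, seed=9,
                         sigma_phylo=0.0, sigma_iid=0.0)
        doubled = SimConfig(n_species=30, n_families=40, seed=9,
                            causal_weights=tuple(
                                2 * w for w in base.causal_weights),
                            sigma_phylo=0.0, sigma_iid=0.0)
        tree, counts, causal = self.make(base)
        v1 = assign_trait(counts, tree, base, causal).liability.var()
        v2 = assign_trait(counts, tree, doubled, causal).liability.var()
        assert v2 == pytest.approx(4 * v1, rel=1e-9)

    def test_liability_reproducible_from_recorded_draws(self, small_dataset):
        truth = small_dataset.truth
        counts = small_dataset.counts
        w = truth.causal_weights
        recomputed = (
            counts[sorted(w)] @ pd.Series(w)
            + truth.bm_noise + truth.iid_noise
        )
        np.testing.assert_allclose(truth.liability, recomputed, atol=1e-9)


class TestEmitGrowthCurves:
    def sample_truth(self, r_values, cfg):
        import pandas as pd
        from famtrait.simulate import SyntheticTruth

        species = [f"sp{i:04d}" for i in range(len(r_values))]
        r = pd.Series(r_values, index=species)
        zero = pd.Series(0.0, index=species)
        return SyntheticTruth(causal_weights={}, liability=r, resistance=r,
                              bm_noise=zero, iid_noise=zero)

    def test_resistant_limit_ratio_near_one(self):
        cfg = SimConfig(n_species=3, n_families=10, noise_sd=0.0,
                        rate_jitter_sd=0.0, seed=2)
        truth = self.sample_truth([0.999], cfg)
        curves, _, _ = emit_growth_curves(truth, cfg)
        treated = next(c for c in curves if c.dose == 1.0)
        control = next(c for c in curves if c.dose == 0.0)
        assert eauc(treated) / eauc(control) > 0.9

    def test_sensitive_limit_ratio_near_zero(self):
        cfg = SimConfig(n_species=3, n_families=10, noise_sd=0.0,
                        rate_jitter_sd=0.0, seed=2)
        truth = self.sample_truth([0.001], cfg)
        curves, _, _ = emit_growth_curves(truth, cfg)
        treated = next(c for c in curves if c.dose == 2.0)
        control = next(c for c in curves if c.dose == 0.0)
        assert eauc(treated) / eauc(control) < 0.2

    def test_noiseless_curve_matches_quadrature(self):
        cfg = SimConfig(n_species=3, n_families=10, noise_sd=0.0,
                        rate_jitter_sd=0.0, seed=2)
        truth = self.sample_truth([0.5], cfg)
        curves, _, _ = emit_growth_curves(truth, cfg)
        control = next(c for c in curves if c.dose == 0.0)
        n0, k = cfg.n0, cfg.k0
        # recover the realized rate from the curve itself at t=1
        od1 = control.od[1]
        rho = -np.log((k / od1 - 1) / ((k - n0) / n0))
        exact, _ = quad(
            lambda t: k / (1 + ((k - n0) / n0) * np.exp(-rho * t)),
            0, cfg.duration_h,
        )
        assert eauc(control) == pytest.approx(exact, rel=1e-4)


class TestMakeDataset:
    def test_labels_follow_the_tail_rule(self, small_dataset, small_config):
        f = small_config.tail_fraction
        n = small_config.n_species
        assert len(small_dataset.classes.sensitive) == int(f * n)
        assert len(small_dataset.classes.resistant) == int(f * n)
        assert small_dataset.instances.shape[0] == 2 * int(f * n)
        # class labels recomputable from emitted phenotypes
        again = classify_tails(small_dataset.phenotypes, 1.0, 2.0, f=f)
        assert again.labels == small_dataset.classes.labels

    def test_files_load_with_package_readers(self, small_dataset, small_config, tmp_path):
        from famtrait.simulate import _write_dataset

        _write_dataset(small_dataset, tmp_path)
        counts = read_orthogroup_counts(tmp_path / "gene_counts.tsv")
        pd.testing.assert_frame_equal(counts, small_dataset.counts,
                                      check_names=False)
        membership = read_membership(tmp_path / "membership.tsv")
        assert membership == small_dataset.membership
        tree = read_newick(tmp_path / "tree.nwk")
        assert tree.tips == small_dataset.tree.tips
        curves = read_plate_table(
            tmp_path / "plate.csv",
            read_well_metadata(tmp_path / "metadata.csv"),
        )
        recs = phenotype_table(curves)
        by_key = {(r.species, r.dose): r.relative_growth for r in recs}
        for rec in small_dataset.phenotypes:
            assert by_key[(rec.species, rec.dose)] == pytest.approx(
                rec.relative_growth, rel=1e-9
            )
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["class_labels"] == small_dataset.truth.class_labels

    def test_same_seed_byte_identical_outputs(self, small_config, tmp_path):
        import hashlib

        from famtrait.simulate import _write_dataset

        hashes = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            _write_dataset(make_dataset(small_config), out)
            digest = {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
            }
            hashes.append(digest)
        assert hashes[0] == hashes[1]

    def test_different_seed_different_counts_same_shapes(self, small_config,
                                                         small_dataset):
        other = make_dataset(SimConfig(n_species=60, n_families=150, seed=8))
        assert other.counts.shape == small_dataset.counts.shape
        assert not other.counts.equals(small_dataset.counts)

    def test_annotations_mark_causal_genes(self, small_dataset):
        ref = small_dataset.counts.index[0]
        causal_genes = {
            g
            for og in small_dataset.truth.causal_families
            for g in small_dataset.membership[og][ref]
        }
        if causal_genes:
            assert causal_genes <= small_dataset.annotations["causal_term"]
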