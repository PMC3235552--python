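"""Synthetic library generation and dual-screen simulation."""

import dataclasses
import filecmp

import numpy as np
import pytest

from fragxscreen.chem import compute_descriptors
from fragxscreen.filters import evaluate_fragment_rules
from fragxscreen.screen import classify
from fragxscreen.synth import (
    GeneratorConfig,
    ReceptorModel,
    default_config,
    default_receptor_models,
    generate_library,
    latent_pki,
    make_fixture_bundle,
    percent_cutoff,
    percent_effect_from_pki,
    pharmacophore_features,
    simulate_dual_screen,
)


class TestGenerateLibrary:
    def test_size_zero(self):
        assert generate_library(dataclasses.replace(default_config(), library_size=0)) == []

    def test_deterministic_per_seed(self):
        lib1 = generate_library(default_config(seed=5))
        lib2 = generate_library(default_config(seed=5))
        assert [m.smiles for m in lib1] == [m.smiles for m in lib2]

    def test_different_seeds_differ(self):
        lib1 = generate_library(dataclasses.replace(default_config(seed=1), library_size=50))
        lib2 = generate_library(dataclasses.replace(default_config(seed=2), library_size=50))
        assert [m.smiles for m in lib1] != [m.smiles for m in lib2]

    def test_every_output_passes_fragment_rules(self, default_library):
        for m in default_library:
            verdict = evaluate_fragment_rules(compute_descriptors(m), m)
            assert verdict.passed, (m.identifier, m.smiles, verdict.failed_rules)

    def test_unique_structures_and_ids(self, default_library):
        smiles = [m.smiles for m in default_library]
        ids = [m.identifier for m in default_library]
        assert len(set(smiles)) == len(smiles)
        assert len(set(ids)) == len(ids)

    def test_oversized_request_reports_achievable_count(self):
        cfg = dataclasses.replace(default_config(), library_size=10**6)
        with pytest.raises(ValueError, match=r"only \d+ rule-compliant"):
            generate_library(cfg)


class TestLatentAffinity:
    def test_zero_weights_give_baseline(self, default_library):
        receptor = ReceptorModel(
            name="null", baseline_pki=4.2, weights=(), scaffold_bonuses=(), noise_sd=0.0
        )
        assert latent_pki(default_library[0], receptor) == 4.2

    def test_donor_weight_is_linear(self, fixture_molecules):
        hist = fixture_molecules["histamine"]
        base = ReceptorModel(name="r", baseline_pki=3.0, weights=(), scaffold_bonuses=())
        with_hbd = dataclasses.replace(base, weights=(("hbd", 0.7),))
        n_donors = pharmacophore_features(hist)["hbd"]
        assert latent_pki(hist, with_hbd) == pytest.approx(3.0 + 0.7 * n_donors)

    def test_unknown_feature_rejected(self, fixture_molecules):
        receptor = ReceptorModel(
            name="r", baseline_pki=3.0, weights=(("quantum", 1.0),), scaffold_bonuses=()
        )
        with pytest.raises(KeyError, match="quantum"):
            latent_pki(fixture_molecules["benzene"], receptor)

    def test_monte_carlo_mean_matches_analytic(self, default_library):
        receptor = default_receptor_models()[0]
        m = default_library[0]
        analytic = latent_pki(m, receptor)
        rng = np.random.default_rng(123)
        draws = [latent_pki(m, receptor, rng.normal(0, receptor.noise_sd)) for _ in range(1000)]
        se = receptor.noise_sd / np.sqrt(len(draws))
        assert abs(np.mean(draws) - analytic) < 3 * se

    def test_pharmacophore_features_sane(self, fixture_molecules):
        f = pharmacophore_features(fixture_molecules["methylpiperazine_phenyl"])
        assert f["has_ionizable_ring"] == 1.0
        assert f["basic_amine"] == 1.0  # aniline-type N not basic
        assert f["aromatic_rings"] == 1.0
        f2 = pharmacophore_features(fixture_molecules["benzimidazole"])
        assert f2["scaffold:benzimidazole"] == 1.0
        assert f2["scaffold:imidazole"] == 0.0  # fused ring does not count


class TestSimulateDualScreen:
    def test_threshold_above_everything_gives_no_hits(self, default_library):
        model_a, model_b = default_receptor_models()
        hi_a = dataclasses.replace(model_a, hit_threshold_pki=99.0)
        hi_b = dataclasses.replace(model_b, hit_threshold_pki=99.0)
        _sa, _sb, truth = simulate_dual_screen(default_library[:50], hi_a, hi_b, seed=1)
        assert not truth.hits_a and not truth.hits_b

    def test_deterministic_per_seed(self, default_library):
        model_a, model_b = default_receptor_models()
        lib = default_library[:100]
        sa1, _, t1 = simulate_dual_screen(lib, model_a, model_b, seed=9)
        sa2, _, t2 = simulate_dual_screen(lib, model_a, model_b, seed=9)
        assert sa1.equals(sa2)
        assert t1.as_mapping() == t2.as_mapping()

    def test_percent_effect_monotone_in_pki_and_consistent(self, default_screen):
        screen_a, _sb, _t = default_screen
        hits = screen_a[screen_a["is_hit"]]
        model_a = default_receptor_models()[0]
        assert (hits["percent_effect"] >= percent_cutoff(model_a) - 1e-9).all()
        pki = np.linspace(2, 9, 50)
        eff = percent_effect_from_pki(pki, 10.0)
        assert (np.diff(eff) > 0).all()
        assert percent_effect_from_pki(5.0, 10.0) == pytest.approx(50.0)

    def test_truth_matches_reclassification_from_screens(self, default_screen, default_library):
        screen_a, screen_b, truth = default_screen
        rederived = classify(
            screen_a, screen_b, [m.identifier for m in default_library],
            target_a=truth.target_a, target_b=truth.target_b,
        )
        assert rederived.as_mapping() == truth.as_mapping()


class TestFixtureBundle:
    def test_bundle_reproducible_and_reloadable(self, tmp_path):
        cfg = dataclasses.replace(default_config(), library_size=120)
        p1 = make_fixture_bundle(3, tmp_path / "one", cfg=cfg)
        p2 = make_fixture_bundle(3, tmp_path / "two", cfg=cfg)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_bundle_truth_matches_pipeline_classification(self, tmp_path):
        import pandas as pd

        from fragxscreen.chem import read_smiles_file
        from fragxscreen.screen import call_hits

        cfg = dataclasses.replace(default_config(), library_size=150)
        models = default_receptor_models()
        paths = make_fixture_bundle(4, tmp_path / "bundle", cfg=cfg, models=models)
        lib = read_smiles_file(paths["library"])
        screen_a = call_hits(pd.read_csv(paths["screen_a"]), cutoff=percent_cutoff(models[0]))
        screen_b = call_hits(pd.read_csv(paths["screen_b"]), cutoff=percent_cutoff(models[1]))
        c = classify(screen_a, screen_b, [m.identifier for m in lib])
        truth = pd.read_csv(paths["truth"]).set_index("fragment_id")["hit_class"].to_dict()
        assert c.as_mapping() == truth

    def test_two_seeds_differ(self, tmp_path):
        cfg = dataclasses.replace(default_config(), library_size=60)
        p1 = make_fixture_bundle(1, tmp_path / "s1", cfg=cfg)
        p2 = make_fixture_bundle(2, tmp_path / "s2", cfg=cfg)
        assert not filecmp.cmp(p1["library"], p2["library"], shallow=False)
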