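"""Planted-module generator and the HNSCC-like cohort fixture."""

import numpy as np
import pytest

from paretomut import (
    COVERAGE_SIZE,
    ConfigurationError,
    GeneSelection,
    PlantedModuleConfig,
    coverage,
    generate_hnsc_fixture,
    generate_planted,
    hnsc_preprocess,
    overlap,
    pareto_front_exact,
)
from paretomut.io import filter_samples, regroup_attribute
from paretomut.synthetic import HNSC_SITE_MAP


class TestGeneratePlanted:
    def test_noise_free_module_covers_everything_exclusively(self):
        cfg = PlantedModuleConfig(n_samples=100, modules=(4,),
                                  module_coverage=1.0, module_overlap_rate=0.0,
                                  n_noise_genes=0, noise_rate=0.0, seed=1)
        matrix, modules = generate_planted(cfg)
        sel = GeneSelection(modules[0])
        assert coverage(sel, matrix) == 100
        assert overlap(sel, matrix) == 0

    def test_coverage_is_exact_without_replacement(self):
        cfg = PlantedModuleConfig(n_samples=1000, module_coverage=0.9,
                                  n_noise_genes=0, seed=2)
        matrix, modules = generate_planted(cfg)
        assert coverage(GeneSelection(modules[0]), matrix) == 900

    def test_overlap_rate_injection(self):
        cfg = PlantedModuleConfig(n_samples=1000, module_coverage=1.0,
                                  module_overlap_rate=0.2, n_noise_genes=0,
                                  seed=3)
        matrix, modules = generate_planted(cfg)
        rate = overlap(GeneSelection(modules[0]), matrix) / 1000
        assert rate == pytest.approx(0.2, abs=0.04)

    def test_noise_frequency_converges_to_rate(self):
        cfg = PlantedModuleConfig(n_samples=10_000, modules=(2,),
                                  n_noise_genes=5, noise_rate=0.05, seed=4)
        matrix, _ = generate_planted(cfg)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        for g in matrix.gene_ids:
            if g.startswith("NOISE"):
                freq = matrix.gene_counts()[g] / 10_000
                assert abs(freq - 0.05) <= 3 * se

    def test_seed_determinism_and_invariants(self):
        cfg = PlantedModuleConfig(seed=5)
        a, mods_a = generate_planted(cfg)
        b, mods_b = generate_planted(cfg)
        assert a.equals(b) and mods_a == mods_b
        assert len(set(a.gene_ids)) == a.n_genes
        assert set(a.values.ravel()) <= {0, 1}

    def test_planted_module_is_the_unique_size_optimal_set(self):
        # noise-free small instance: the module must be the exact size-k
        # coverage maximizer found by brute force
        cfg = PlantedModuleConfig(n_samples=40, modules=(3,),
                                  module_coverage=0.9, n_noise_genes=4,
                                  noise_rate=0.0, seed=6)
        matrix, modules = generate_planted(cfg)
        ps = pareto_front_exact(matrix, mode=COVERAGE_SIZE)
        size3 = [sel for sel, vec in ps.entries if vec.second == 3]
        assert size3 and set(size3[0].members) == set(modules[0])

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            PlantedModuleConfig(module_coverage=1.2)
        with pytest.raises(ConfigurationError):
            PlantedModuleConfig(modules=(1,), module_overlap_rate=0.5)


@pytest.fixture(scope="module")
def fixture():
    return generate_hnsc_fixture(seed=0)


class TestHnscFixture:
    def test_reference_group_counts(self, fixture):
        expr, clinical = fixture
        sites = clinical.data["PRIMARY_SITE"].value_counts()
        assert len(expr.sample_ids) == 522
        assert sites["Lip"] == 2
        assert sites["Hypopharynx"] == 10

    def test_full_pipeline_reproduces_cohort_shape(self, fixture):
        expr, clinical = fixture
        matrix, out_clinical, info = hnsc_preprocess(expr, clinical)
        assert info["deleted"] == {"lip": 2, "hypopharynx": 10,
                                   "missing HPV status": 19}
        assert matrix.n_samples == 491
        assert matrix.n_genes == 208
        assert out_clinical.sample_ids == matrix.sample_ids
        # harmonized to the four retained sites
        assert set(out_clinical.data["PRIMARY_SITE"]) == {
            "oral cavity", "oropharynx", "larynx"}

    def test_site_deletions_alone_leave_510(self, fixture):
        expr, clinical = fixture
        harmonized = regroup_attribute(clinical, "PRIMARY_SITE", HNSC_SITE_MAP)
        from paretomut.io import binarize_expression
        matrix = binarize_expression(expr)
        out, _, _ = filter_samples(matrix, harmonized, [
            ("lip", "PRIMARY_SITE", "eq", "lip"),
            ("hypopharynx", "PRIMARY_SITE", "eq", "hypopharynx"),
        ])
        assert out.n_samples == 510

    def test_same_seed_regenerates_identical_fixture(self, fixture):
        expr, clinical = fixture
        expr2, clinical2 = generate_hnsc_fixture(seed=0)
        assert expr.data.equals(expr2.data)
        assert clinical.equals(clinical2)

    def test_gene_filters_are_tight(self, fixture):
        expr, clinical = fixture
        matrix, _, _ = hnsc_preprocess(expr, clinical)
        # every surviving gene clears the 5% in-cohort frequency bar
        freqs = matrix.gene_counts() / matrix.n_samples
        assert (freqs >= 0.05).all()
        assert all(g.startswith("CTA") for g in matrix.gene_ids)
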