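"""Synthetic panel generation and the depth/allele-dropout error model."""

import numpy as np
import pandas as pd
import pytest

from ramdecode import fixtures
from ramdecode.genotype_io import PloidyModel
from ramdecode.synthetic_data import (
    DepthModel,
    PanelSpec,
    analytic_het_dropout,
    default_panel_spec,
    generate_ortholog_set,
    generate_panel,
    generate_reference_truth,
    simulate_depth_and_calls,
)
from ramdecode.wgs_qc import genotype_accuracy


class TestGeneratePanel:
    def test_fixed_haplotype_gives_zero_variance(self):
        spec = default_panel_spec(n_per_breed=20, seed=1)
        # White Dorper BMP15 is fixed for variant 3 in the defaults
        panel, matrix, truth = generate_panel(spec)
        wd = [a for a in panel.animals
              if panel.breed_of(a) == "White Dorper"]
        v3 = fixtures.haplotype_vectors("BMP15")["3"]
        assert all(truth["BMP15"][a] == (v3,) for a in wd)

    def test_male_x_has_exactly_one_haplotype(self):
        spec = default_panel_spec(n_per_breed=10, seed=2)
        _, matrix, truth = generate_panel(spec)
        assert all(len(h) == 1 for h in truth["BMP15"].values())
        assert all(len(h) == 2 for h in truth["GDF9"].values())
        x_sites = [s.site_id for s in matrix.sites if s.chrom == "chrX"]
        for sid in x_sites:
            assert all(len(matrix.get(a, sid)) == 1 for a in matrix.animals)

    def test_reproducible_from_seed(self):
        a = generate_panel(default_panel_spec(n_per_breed=15, seed=9))
        b = generate_panel(default_panel_spec(n_per_breed=15, seed=9))
        assert a[2] == b[2]
        pd.testing.assert_frame_equal(a[1].calls, b[1].calls)

    def test_different_seeds_differ(self):
        a = generate_panel(default_panel_spec(n_per_breed=15, seed=9))
        b = generate_panel(default_panel_spec(n_per_breed=15, seed=10))
        assert a[2] != b[2]
        assert list(a[1].calls.columns) == list(b[1].calls.columns)

    def test_invalid_frequency_vector_rejected(self):
        spec = default_panel_spec(n_per_breed=5)
        gs = spec.genes["GDF9"]
        bad = dict(gs.breed_freqs)
        bad["Texel"] = {"1": 0.5, "2": 0.2}  # sums to 0.7
        object.__setattr__(gs, "breed_freqs", bad)
        with pytest.raises(ValueError, match="sum"):
            PanelSpec(breeds=spec.breeds, genes={"GDF9": gs})

    def test_genotype_is_unordered_union_of_truth(self):
        spec = default_panel_spec(n_per_breed=8, seed=4)
        panel, matrix, truth = generate_panel(spec)
        gs = spec.genes["GDF9"]
        for a in panel.animals[:20]:
            haps = truth["GDF9"][a]
            for k, sid in enumerate(gs.site_ids):
                expected = tuple(sorted(
                    gs.allele_map[(k, h[k])] for h in haps))
                assert matrix.get(a, sid) == expected


class TestDepthModel:
    def test_truncation_minimum(self):
        rng = np.random.default_rng(0)
        d = DepthModel(location=2.0, spread=3.0).draw(rng, 5000)
        assert d.min() >= 1

    def test_sample_mean_matches_location(self):
        rng = np.random.default_rng(1)
        d = DepthModel().draw(rng, 40_000)
        se = 3.5 / np.sqrt(40_000)
        assert abs(d.mean() - 16.8) < 3 * se + 0.05


class TestSimulateDepthAndCalls:
    def _het_matrix(self, n):
        spec = default_panel_spec(n_per_breed=1, seed=0)
        gs = spec.genes["BMPR1B"]
        from ramdecode.gene_models import VariantSite
        from ramdecode.genotype_io import GenotypeMatrix

        site = [s for s in fixtures.variant_sites()
                if s.site_id == "BMPR1B:M64I"][0]
        animals = [f"an{i}" for i in range(n)]
        m = GenotypeMatrix([site], animals)
        for a in animals:
            m.set(a, site.site_id, ("c", "t"))
        return m, site.site_id

    def test_below_min_depth_is_missing(self):
        m, sid = self._het_matrix(200)
        obs = simulate_depth_and_calls(
            m, DepthModel(location=2.0, spread=1e-9), min_depth=3, seed=1)
        assert all(obs.get(a, sid) is None for a in obs.animals)
        assert (obs.depths[sid] == 2).all()

    def test_het_dropout_at_depth_3_is_one_quarter(self):
        """P(erroneous hom | het, d=3) = 2 * (1/2)^3 = 0.25, checked by
        Monte-Carlo at n=100,000 within 3 SE."""
        n = 100_000
        m, sid = self._het_matrix(n)
        obs = simulate_depth_and_calls(
            m, DepthModel(location=3.0, spread=1e-9), min_depth=3, seed=2)
        hom = sum(len(set(obs.get(a, sid))) == 1 for a in obs.animals)
        p = hom / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(p - 0.25) <= 3 * se

    def test_high_depth_het_always_called(self):
        m, sid = self._het_matrix(500)
        obs = simulate_depth_and_calls(
            m, DepthModel(location=1000.0, spread=1e-9), seed=3)
        assert all(obs.get(a, sid) == ("c", "t") for a in obs.animals)

    def test_hom_cells_never_err_without_miscalls(self):
        spec = default_panel_spec(n_per_breed=50, seed=5)
        panel, truth_m, _ = generate_panel(spec)
        obs = simulate_depth_and_calls(truth_m, DepthModel(), seed=6)
        for sid in truth_m.site_ids:
            for a in truth_m.animals:
                t, o = truth_m.get(a, sid), obs.get(a, sid)
                if o is None or len(set(t)) != 1:
                    continue
                assert o == t

    def test_analytic_matches_monte_carlo(self):
        model = DepthModel(location=6.0, spread=2.0)
        expected = analytic_het_dropout(model, min_depth=3)
        n = 60_000
        m, sid = self._het_matrix(n)
        obs = simulate_depth_and_calls(m, model, min_depth=3, seed=7)
        scored = [a for a in obs.animals if obs.get(a, sid) is not None]
        hom = sum(len(set(obs.get(a, sid))) == 1 for a in scored)
        p = hom / len(scored)
        se = np.sqrt(expected * (1 - expected) / len(scored))
        assert abs(p - expected) <= 3 * se


class TestReferenceTruth:
    def test_four_errors_in_163(self):
        truth, corrupted = generate_reference_truth(1, 163, 4, seed=0)
        t = {(r.animal_id, r.site_id): tuple(r.genotype.split("/"))
             for r in truth.itertuples(index=False)}
        c = {(r.animal_id, r.site_id): tuple(r.genotype.split("/"))
             for r in corrupted.itertuples(index=False)}
        errors, compared, pct = genotype_accuracy(c, t)
        assert (errors, compared) == (4, 163)
        assert round(pct, 2) == 97.55

    def test_zero_and_all_errors(self):
        truth, same = generate_reference_truth(2, 30, 0, seed=1)
        assert truth.equals(same)
        truth, corrupted = generate_reference_truth(1, 30, 30, seed=2)
        t = {(r.animal_id, r.site_id): tuple(r.genotype.split("/"))
             for r in truth.itertuples(index=False)}
        c = {(r.animal_id, r.site_id): tuple(r.genotype.split("/"))
             for r in corrupted.itertuples(index=False)}
        assert genotype_accuracy(c, t)[2] == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            generate_reference_truth(1, 0, 0)


class TestGenerateOrthologSet:
    def test_spec_recovery(self):
        from ramdecode.conservation import conservation_depth

        out = generate_ortholog_set(
            fixtures.SPECIES_CLADES, fixtures.CLADE_LADDER,
            {"G:1": {"reference_residue": "T",
                     "conserved_through": "Tetrapoda"}}, seed=0)
        assert conservation_depth(out.column("G:1"), out.clade_paths, "T",
                                  out.ladder) == "Tetrapoda"

    def test_exception_species_listed(self):
        from ramdecode.conservation import conservation_exceptions

        out = generate_ortholog_set(
            fixtures.SPECIES_CLADES, fixtures.CLADE_LADDER,
            {"G:1": {"reference_residue": "M",
                     "conserved_through": "Theria",
                     "exceptions": {"human": "V", "manatee": "V"}}}, seed=0)
        _, exc = conservation_exceptions(out.column("G:1"), out.clade_paths,
                                         "M", out.ladder, max_exceptions=2)
        assert exc == ("human", "manatee")

    def test_empty_taxonomy_errors(self):
        with pytest.raises(ValueError):
            generate_ortholog_set({}, (), {}, seed=0)


class TestEndToEndRecovery:
    def test_decode_recovers_spec_frequencies(self):
        """Panel-wide frequencies decoded from a generated panel fall within
        3 binomial SE of the generating frequencies, and phase status is
        unambiguous or correctly inferred for every individual."""
        from ramdecode.pipeline import decode_panel

        n = 1500
        spec = default_panel_spec(n_per_breed=n, seed=77)
        panel, matrix, truth = generate_panel(spec)
        result = decode_panel(matrix, panel, with_conservation=False)
        sizes = panel.breed_counts()
        for gene, gs in spec.genes.items():
            factor = 1 if PloidyModel().is_x(gs.chrom) else 2
            n_chrom = sum(sizes.values()) * factor
            expected = {}
            for breed, freqs in gs.breed_freqs.items():
                w = sizes[breed] * factor / n_chrom
                for code, p in freqs.items():
                    key = ",".join(gs.vectors[code])
                    expected[key] = expected.get(key, 0.0) + w * p
            ft = result.hap_tables[gene].table
            for _, row in ft.iterrows():
                p = expected[row["residues"]]
                se = np.sqrt(p * (1 - p) / n_chrom)
                assert abs(row["frequency"] - p) <= 3 * se + 1e-9
            # phase correctness: every non-unresolved phase matches truth
            wrong = 0
            for ind in result.phased[gene]:
                t = tuple(sorted(truth[gene][ind.animal]))
                if ind.status != "unresolved" and \
                        tuple(sorted(ind.haplotypes)) != t:
                    wrong += 1
            assert wrong == 0
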