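import numpy as np
import pytest

from breedvar import density, setcompare, synthdata, validation, variant_io
from breedvar.synthdata import SimulationConfig


class TestGeneModels:
    def test_count_and_validity(self, sim_config):
        models = synthdata.gen_gene_models(sim_config)
        assert len(models) == sim_config.n_genes
        assert all(m.end >= m.start for m in models)

    def test_lengths_within_configured_range(self):
        cfg = SimulationConfig(seed=3, n_genes=50, gene_length_range_bp=(1000, 5000))
        models = synthdata.gen_gene_models(cfg)
        assert all(1000 <= m.length_bp <= 5000 for m in models)

    def test_non_overlapping(self, sim_config):
        models = synthdata.gen_gene_models(sim_config)
        ordered = sorted(models, key=lambda m: m.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end < b.start

    def test_deterministic_under_seed(self, sim_config):
        a = synthdata.gen_gene_models(sim_config)
        b = synthdata.gen_gene_models(SimulationConfig(seed=sim_config.seed))
        assert a == b

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            synthdata.gen_gene_models(SimulationConfig(gene_length_range_bp=(500, 100)))


class TestVariantTables:
    def test_shared_fraction_one_degenerate(self):
        cfg = SimulationConfig(seed=5, shared_fraction=1.0, n_variants_per_breed=50)
        tables, truth = synthdata.gen_variant_tables(cfg)
        keys = [setcompare.variant_keys(t) for t in tables.values()]
        assert keys[0] == keys[1] == keys[2]
        part = setcompare.threeway_partition(*keys)
        assert len(part.cells["ABC"]) == 50 == truth["cells"]["ABC"]

    def test_shared_fraction_zero_empty_core(self):
        cfg = SimulationConfig(seed=5, shared_fraction=0.0, n_variants_per_breed=50)
        tables, _ = synthdata.gen_variant_tables(cfg)
        part = setcompare.threeway_partition(*(setcompare.variant_keys(t) for t in tables.values()))
        assert not part.cells["ABC"]

    def test_partition_matches_truth_log(self, variant_tables):
        _, tables, truth = variant_tables
        keys = {b: setcompare.variant_keys(t) for b, t in tables.items()}
        part = setcompare.threeway_partition(
            keys["LES"], keys["SER"], keys["THR"], labels=("LES", "SER", "THR")
        )
        sizes = part.sizes()
        assert sizes["ABC"] == truth["cells"]["ABC"]
        for breed, cell in (("LES", "A_only"), ("SER", "B_only"), ("THR", "C_only")):
            assert sizes[cell] == truth["cells"][f"{breed}_only"]

    def test_truth_totals_conserved(self, variant_tables):
        _, tables, truth = variant_tables
        for breed, records in tables.items():
            assert sum(truth["class_counts"][breed].values()) == len(records)
            assert truth["n_missense"][breed] + truth["n_exonic_indels"][breed] <= len(records)

    def test_deterministic_serialization(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_variants_per_breed=40)
        paths = []
        for run in ("a", "b"):
            tables, _ = synthdata.gen_variant_tables(cfg)
            p = tmp_path / f"{run}.tsv"
            variant_io.write_variant_tsv(tables["LES"], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestPipelineClosure:
    def test_generated_outputs_flow_through_all_stages(self, tmp_path, variant_tables):
        models, tables, truth = variant_tables
        lengths = density.compute_gene_lengths(models)
        for breed, records in tables.items():
            vcf = tmp_path / f"{breed}.vcf"
            synthdata.write_vcf(records, vcf)
            parsed = variant_io.read_variant_table(vcf, "vcf")
            kept, report = variant_io.apply_quality_filters(parsed)
            assert report.n_removed == 0  # default generator passes thresholds
            exonic = tmp_path / f"{breed}.exonic"
            synthdata.write_annovar_exonic(records, exonic)
            annotated = variant_io.normalize_and_dedupe(
                variant_io.read_variant_table(exonic, "annovar_exonic")
            )
            assert len(annotated) == len(records)
            snps = density.select_missense(annotated)
            indels = density.select_exonic_indels(annotated)
            assert len(snps) == truth["n_missense"][breed]
            assert len(indels) == truth["n_exonic_indels"][breed]
            recs, missing = density.compute_density(snps, indels, lengths)
            assert not missing


class TestGenotypes:
    def test_af_zero_all_homozygous_ref(self):
        cfg = SimulationConfig(seed=2, missing_rate=0.0)
        spec = synthdata.panel_af_spec(cfg)
        for b in cfg.breeds:
            spec[f"af_{b}"] = 0.0
        matrix, _ = synthdata.gen_genotypes(cfg, spec)
        assert all(
            pair == ("A", "A") for col in matrix.calls.values for pair in col
        )

    def test_af_one_all_homozygous_alt(self):
        cfg = SimulationConfig(seed=2, missing_rate=0.0)
        spec = synthdata.panel_af_spec(cfg)
        for b in cfg.breeds:
            spec[f"af_{b}"] = 1.0
        matrix, _ = synthdata.gen_genotypes(cfg, spec)
        assert all(pair == ("G", "G") for col in matrix.calls.values for pair in col)

    def test_out_of_range_af_rejected(self):
        cfg = SimulationConfig(seed=2)
        spec = synthdata.panel_af_spec(cfg)
        spec.loc[0, "af_LES"] = 1.5
        with pytest.raises(ValueError):
            synthdata.gen_genotypes(cfg, spec)

    def test_empirical_af_converges(self):
        cfg = SimulationConfig(seed=8, n_animals_per_breed=2000, missing_rate=0.0, n_snps_panel=46)
        spec = synthdata.panel_af_spec(cfg)
        spec_one = spec.iloc[:1].copy()
        for b in cfg.breeds:
            spec_one[f"af_{b}"] = 0.5
        matrix, _ = synthdata.gen_genotypes(cfg, spec_one)
        freqs = validation.allele_frequencies(matrix, {spec_one.snp_id[0]: ("A", "G")})
        se = np.sqrt(0.5 * 0.5 / (2 * 2000))
        for breed, (_, _, _, af) in freqs[0].by_breed.items():
            assert abs(af - 0.5) < 3 * se

    def test_determinism(self):
        cfg = SimulationConfig(seed=21)
        m1, _ = synthdata.gen_genotypes(cfg)
        m2, _ = synthdata.gen_genotypes(cfg)
        assert m1.calls.equals(m2.calls)

    def test_missingness_rate_plausible(self):
        cfg = SimulationConfig(seed=4, missing_rate=0.05)
        matrix, _ = synthdata.gen_genotypes(cfg)
        frac = matrix.calls.isna().to_numpy().mean()
        assert 0.02 < frac < 0.08


class TestPanelFixture:
    def test_row_count(self, panel):
        assert len(panel) == 46

    def test_spot_rows(self, panel):
        row = panel.set_index("snp_id").loc["rs422734187"]
        assert (row.af_LES, row.af_SER, row.af_THR) == (0.72, 0.17, 0.24)
        assert panel.set_index("snp_id").loc["rs412607607", "pattern"] == "Shared"

    def test_composition(self, panel):
        assert (panel.wgs_class == "Common").sum() == 16
        assert panel.wgs_class.str.endswith("-specific").sum() == 30
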