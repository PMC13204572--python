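import itertools
import random

import numpy as np
import pandas as pd
import pytest
from oracles import bh_stepup, fisher_p_exact

from breedvar import synthdata, validation
from breedvar.validation import (
    ClassifierConfig,
    allele_frequencies,
    bh_adjust,
    chisq_test,
    choose_test,
    classify_pattern,
    fisher_exact_2xc,
    load_genotypes,
    qc_call_rates,
    reconstruct_counts,
)


class TestFisherExact:
    def test_hand_enumeration_2x2(self):
        # margins (2,2)/(2,2): three tables with probs 1/6, 4/6, 1/6
        assert fisher_exact_2xc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_identical_columns_give_one(self):
        assert fisher_exact_2xc([[10, 10, 10], [26, 26, 26]]) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact

        rnd = np.random.default_rng(5)
        for _ in range(200):
            t = rnd.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2xc(t) == pytest.approx(fisher_exact(t)[1], rel=1e-9)

    def test_matches_bruteforce_oracle_random_2x3(self):
        rnd = random.Random(17)
        for _ in range(150):
            t = [[rnd.randrange(12) for _ in range(3)] for _ in range(2)]
            if sum(map(sum, t)) == 0:
                continue
            assert fisher_exact_2xc(t) == pytest.approx(float(fisher_p_exact(t)), rel=1e-9)

    def test_column_permutation_and_row_swap_invariance(self):
        rnd = np.random.default_rng(9)
        for _ in range(25):
            t = rnd.integers(0, 15, size=(2, 3))
            if t.sum() == 0:
                continue
            p = fisher_exact_2xc(t)
            for perm in itertools.permutations(range(3)):
                assert fisher_exact_2xc(t[:, perm]) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2xc(t[::-1]) == pytest.approx(p, rel=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xc([[1], [2]])  # single column
        with pytest.raises(ValueError):
            fisher_exact_2xc([[1, -1], [2, 3]])


class TestChisq:
    def test_identical_columns(self):
        stat, p = chisq_test([[10, 10], [26, 26]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_statistic(self):
        stat, _ = chisq_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(6.6667, abs=1e-4)

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError, match="expected"):
            chisq_test([[0, 0], [5, 7]])

    def test_asymptotic_agreement_with_exact(self):
        rnd = np.random.default_rng(23)
        for _ in range(10):
            base = rnd.integers(80, 140, size=3)
            t = np.vstack([base + rnd.integers(0, 8, size=3), base])
            _, p_chi = chisq_test(t)
            assert abs(p_chi - fisher_exact_2xc(t)) < 0.02


class TestChooseTest:
    def test_low_expected_uses_fisher(self):
        # smallest expected count 40*8/80 = 4 < 5
        t = [[2, 6, 32], [6, 2, 32]]
        _, method = choose_test(t)
        assert method == "fisher"

    def test_high_expected_uses_chisq(self):
        t = [[20, 25, 30], [22, 28, 26]]
        _, method = choose_test(t)
        assert method == "chisq"

    def test_fisher_always_mode(self):
        t = [[20, 25, 30], [22, 28, 26]]
        p, method = choose_test(t, mode="fisher-always")
        assert method == "fisher"
        assert p == pytest.approx(fisher_exact_2xc(t))


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 0.5, 0.9, 0.04], [0.004, 0.6667, 0.9, 0.08]),
        ],
    )
    def test_hand_stepup(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-4)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_properties_and_oracle_on_random_vectors(self):
        rnd = np.random.default_rng(31)
        for _ in range(300):
            p = rnd.uniform(1e-6, 1.0, size=rnd.integers(1, 40))
            q = np.array(bh_adjust(p))
            assert (q >= p - 1e-12).all() and (q <= 1.0).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert q == pytest.approx(bh_stepup(list(p)))

    def test_explicit_family_size(self):
        # half the family supplied; m fixed at the panel size
        assert bh_adjust([0.01], m=10) == pytest.approx([0.1])
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)


class TestClassifyPattern:
    cfg = ClassifierConfig()

    def test_published_panel_examples(self):
        afs = {"LES": 0.72, "SER": 0.17, "THR": 0.24}
        assert classify_pattern("LES-specific", afs, 1.0e-4, self.cfg).pattern == "Significant"
        afs = {"LES": 0.33, "SER": 0.39, "THR": 0.28}
        call = classify_pattern("SER-specific", afs, 0.62, self.cfg)
        assert call.pattern == "Inconsistent" and call.margin == pytest.approx(0.06)
        afs = {"LES": 0.58, "SER": 0.40, "THR": 0.37}
        call = classify_pattern("LES-specific", afs, 0.084, self.cfg)
        assert call.pattern == "Consistent (NS)" and call.margin == pytest.approx(0.18)
        afs = {"LES": 0.52, "SER": 0.29, "THR": 0.48}
        assert classify_pattern("Common", afs, 0.09, self.cfg).pattern == "Shared"

    def test_target_not_maximum_is_inconsistent_even_if_significant(self):
        afs = {"LES": 0.2, "SER": 0.8, "THR": 0.3}
        assert classify_pattern("LES-specific", afs, 1e-6, self.cfg).pattern == "Inconsistent"

    def test_common_with_significant_q_is_inconsistent(self):
        afs = {"LES": 0.9, "SER": 0.1, "THR": 0.5}
        assert classify_pattern("Common", afs, 0.001, self.cfg).pattern == "Inconsistent"

    def test_margin_exactly_at_delta_counts_as_consistent(self):
        afs = {"LES": 0.48, "SER": 0.40, "THR": 0.30}  # margin 0.08 up to fp
        assert classify_pattern("LES-specific", afs, 0.5, self.cfg).pattern == "Consistent (NS)"

    def test_missing_af_raises(self):
        with pytest.raises(ValueError, match="missing"):
            classify_pattern("LES-specific", {"LES": 0.5, "SER": None, "THR": 0.2}, 0.5, self.cfg)

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            classify_pattern("XXX-specific", {"LES": 0.5, "SER": 0.1, "THR": 0.2}, 0.5, self.cfg)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "af,n,expected",
        [(0.72, 18, (10, 26)), (0.0, 18, (36, 0)), (0.5, 18, (18, 18)), (1.0, 18, (0, 36))],
    )
    def test_round_half_up(self, af, n, expected):
        assert reconstruct_counts(af, n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_counts(1.2, 18)
        with pytest.raises(ValueError):
            reconstruct_counts(0.5, 0)


class TestGenotypeQc:
    def make_matrix(self, missing: dict[str, list[int]], n_samples=4, n_snps=46):
        """Small matrix; ``missing`` maps sample id -> SNP indices set missing."""
        samples = [(f"S{i}", "LES") for i in range(n_samples)]
        snps = [f"snp{j}" for j in range(n_snps)]
        data = {}
        for j, snp in enumerate(snps):
            col = []
            for i, (sid, _) in enumerate(samples):
                col.append(None if j in missing.get(sid, []) else ("A", "G"))
            data[snp] = col
        calls = pd.DataFrame(data, index=[s for s, _ in samples], dtype=object)
        return validation.GenotypeMatrix(samples=samples, snps=snps, calls=calls)

    def test_complete_matrix_untouched(self):
        m = self.make_matrix({})
        out, report = qc_call_rates(m)
        assert out.calls.shape == m.calls.shape
        assert not report["excluded_samples"] and not report["excluded_snps"]

    def test_sample_at_41_of_46_dropped(self):
        m = self.make_matrix({"S0": list(range(5))})  # 41/46 = 0.8913
        out, report = qc_call_rates(m)
        assert report["excluded_samples"] == ["S0"]

    def test_sample_at_42_of_46_retained(self):
        m = self.make_matrix({"S0": list(range(4))})  # 42/46 = 0.9130
        out, report = qc_call_rates(m)
        assert not report["excluded_samples"]

    def test_all_samples_dropped_raises(self):
        m = self.make_matrix({f"S{i}": list(range(10)) for i in range(4)})
        with pytest.raises(ValueError):
            qc_call_rates(m)

    def test_snp_dropped_after_samples(self):
        # one SNP missing in 1 of 4 samples -> 0.75 < 0.9 -> dropped
        m = self.make_matrix({"S0": [0]})
        out, report = qc_call_rates(m)
        assert report["excluded_snps"] == ["snp0"]
        assert "snp0" not in out.snps


class TestAlleleFrequencies:
    def test_hand_counts(self):
        samples = [(f"L{i}", "LES") for i in range(18)]
        # 13 het + 1 hom ref + 4 hom alt -> 13 + 8 = 21 alt alleles? use known mix:
        # 26 alt alleles of 36: 8 hom alt + 10 het
        calls = [("G", "G")] * 8 + [("A", "G")] * 10
        df = pd.DataFrame({"s1": calls}, index=[s for s, _ in samples], dtype=object)
        m = validation.GenotypeMatrix(samples=samples, snps=["s1"], calls=df)
        (rec,) = allele_frequencies(m, {"s1": ("A", "G")})
        n, ref_c, alt_c, af = rec.by_breed["LES"]
        assert (n, ref_c, alt_c) == (18, 10, 26)
        assert af == pytest.approx(26 / 36)

    def test_missing_breed_af_none(self):
        samples = [("L1", "LES"), ("S1", "SER")]
        df = pd.DataFrame({"s1": [("A", "A"), None]}, index=["L1", "S1"], dtype=object)
        m = validation.GenotypeMatrix(samples=samples, snps=["s1"], calls=df)
        (rec,) = allele_frequencies(m, {"s1": ("A", "G")})
        assert rec.by_breed["LES"][3] == 0.0  # monomorphic reference
        assert rec.by_breed["SER"] == (0, 0, 0, None)


class TestLoadGenotypes:
    def test_roundtrip_dimensions(self, tmp_path, sim_config):
        matrix, _ = synthdata.gen_genotypes(sim_config)
        path = tmp_path / "geno.tsv"
        synthdata.write_genotype_tsv(matrix, path)
        back = load_genotypes(path)
        assert back.calls.shape == (54, 46)
        assert back.calls.equals(matrix.calls)

    def test_bad_token_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tbreed\tsnp1\nS1\tLES\tA/G/T\n")
        with pytest.raises(ValueError, match="genotype token"):
            load_genotypes(p)

    def test_unknown_breed_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tbreed\tsnp1\nS1\tMERINO\tA/G\n")
        with pytest.raises(ValueError, match="breed"):
            load_genotypes(p)

    def test_allele_validated_against_ref_alt(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tbreed\tsnp1\nS1\tLES\tA/T\n")
        with pytest.raises(ValueError, match="ref/alt"):
            load_genotypes(p, ref_alt={"snp1": ("A", "G")})


def test_validate_genotypes_end_to_end(sim_config):
    matrix, spec = synthdata.gen_genotypes(sim_config)
    meta = spec[["snp_id", "gene", "wgs_class", "ref", "alt"]]
    out = validation.validate_genotypes(matrix, meta)
    assert len(out) == 46
    assert set(out.columns) >= {"snp_id", "af_LES", "af_SER", "af_THR", "p", "q", "pattern"}
    assert (out.q >= out.p - 1e-12).all()
    # strong designed gap: most breed-specific SNPs recover Significant
    specific = out[out.wgs_class.str.endswith("specific")]
    assert (specific.pattern == "Significant").mean() > 0.7
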