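import math

import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_r
from valuewave import polygenic as pg


def write_sumstats(tmp_path, rows, header="SNP\tA1\tA2\tOR\tP"):
    path = tmp_path / "sumstats.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def make_genotypes(dosages, snp_ids=None, counted=None, alt=None,
                   sample_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return pg.GenotypeMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        snp_ids=snp_ids or [f"rs{j}" for j in range(m)],
        dosages=dosages,
        counted_allele=counted or ["A"] * m,
        alt_allele=alt or ["G"] * m,
    )


def stats_frame(snp_ids, ors=None, ps=None, a1="A", a2="G"):
    m = len(snp_ids)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": [a1] * m,
            "other_allele": [a2] * m,
            "odds_ratio": ors if ors is not None else [1.1] * m,
            "p_value": ps if ps is not None else [0.01] * m,
        }
    )


class TestReadSummaryStats:
    def test_well_formed_file(self, tmp_path):
        path = write_sumstats(
            tmp_path,
            ["rs1\tA\tG\t1.10\t0.01", "rs2\tC\tT\t0.92\t0.40",
             "rs3\tG\tA\t1.00\t0.99"],
        )
        stats = pg.read_summary_stats(path)
        assert len(stats) == 3
        assert stats.loc[1, "odds_ratio"] == pytest.approx(0.92)

    def test_beta_column_exponentiated(self, tmp_path):
        path = write_sumstats(
            tmp_path,
            ["rs1\tA\tG\t0.0\t0.5", "rs2\tA\tG\t0.1\t0.5"],
            header="SNP\tA1\tA2\tBETA\tP",
        )
        stats = pg.read_summary_stats(path, column_map={"beta": "BETA"})
        assert stats.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert stats.loc[1, "odds_ratio"] == pytest.approx(math.exp(0.1))

    def test_duplicate_id_rejected(self, tmp_path):
        path = write_sumstats(
            tmp_path, ["rs1\tA\tG\t1.1\t0.1", "rs1\tC\tT\t1.2\t0.2"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            pg.read_summary_stats(path)

    def test_invalid_rows_named(self, tmp_path):
        path = write_sumstats(tmp_path, ["rs1\tA\tG\t-0.5\t0.1"])
        with pytest.raises(ValueError, match="rs1"):
            pg.read_summary_stats(path)
        path = write_sumstats(tmp_path, ["rs9\tA\tG\t1.1\t1.7"])
        with pytest.raises(ValueError, match="rs9"):
            pg.read_summary_stats(path)


class TestThreshold:
    def test_strict_inequality_at_pt(self):
        stats = stats_frame(["a", "b", "c"], ps=[0.01, 0.49, 0.51])
        kept = pg.threshold_by_p(stats, 0.5)
        assert list(kept["snp_id"]) == ["a", "b"]

    def test_threshold_one_drops_only_p_equal_one(self):
        stats = stats_frame(["a", "b"], ps=[0.9999, 1.0])
        kept = pg.threshold_by_p(stats, 1.0)
        assert list(kept["snp_id"]) == ["a"]

    def test_matches_brute_force_filter(self, rng):
        ps = rng.uniform(0, 1, 50)
        stats = stats_frame([f"rs{j}" for j in range(50)], ps=ps)
        kept = pg.threshold_by_p(stats, 0.3)
        oracle = [f"rs{j}" for j in range(50) if ps[j] < 0.3]
        assert list(kept["snp_id"]) == oracle

    def test_empty_result_errors(self):
        stats = stats_frame(["a"], ps=[0.9])
        with pytest.raises(ValueError, match="no SNPs"):
            pg.threshold_by_p(stats, 0.5)


class TestLdPrune:
    def test_independent_snps_all_retained(self, rng):
        dos = rng.binomial(2, 0.3, size=(500, 6)).astype(float)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids), ps=rng.uniform(0, 0.5, 6))
        pruned = pg.ld_prune_greedy(geno, stats, 0.2)
        assert set(pruned.retained) == set(geno.snp_ids)
        assert pruned.audit == ()

    def test_perfect_pair_keeps_smaller_p(self, rng):
        col = rng.binomial(2, 0.4, size=100).astype(float)
        geno = make_genotypes(np.column_stack([col, col]),
                              snp_ids=["hi_p", "lo_p"])
        stats = stats_frame(["hi_p", "lo_p"], ps=[0.3, 0.01])
        pruned = pg.ld_prune_greedy(geno, stats, 0.2)
        assert pruned.retained == ("lo_p",)
        assert pruned.audit[0][:2] == ("hi_p", "lo_p")
        assert pruned.audit[0][2] == pytest.approx(1.0)

    def test_planted_structure_passes_exhaustive_verification(self, rng):
        # 10 SNPs: pairs (2j, 2j+1) heavily correlated, blocks independent
        n = 400
        cols = []
        for j in range(5):
            base = rng.binomial(2, 0.4, size=n).astype(float)
            noisy = base.copy()
            flip = rng.random(n) < 0.1
            noisy[flip] = rng.binomial(2, 0.4, size=flip.sum())
            cols += [base, noisy]
        dos = np.column_stack(cols)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids), ps=rng.uniform(0, 0.5, 10))
        pruned = pg.ld_prune_greedy(geno, stats, 0.2)

        r2 = pd.DataFrame(dos).corr().to_numpy() ** 2
        idx = {s: j for j, s in enumerate(geno.snp_ids)}
        kept = [idx[s] for s in pruned.retained]
        for i in kept:
            for j in kept:
                if i != j:
                    assert r2[i, j] < 0.2
        removed = set(range(10)) - set(kept)
        for i in removed:
            assert any(r2[i, j] >= 0.2 for j in kept)

    def test_missing_snp_errors_listing_ids(self, rng):
        geno = make_genotypes(rng.binomial(2, 0.3, (50, 2)).astype(float))
        stats = stats_frame(["rs0", "rs1", "rs_absent"])
        with pytest.raises(KeyError, match="rs_absent"):
            pg.ld_prune_greedy(geno, stats, 0.2)


class TestAlignAlleles:
    def test_already_aligned_is_noop(self, rng):
        dos = rng.binomial(2, 0.3, (20, 3)).astype(float)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids))
        aligned, kept = pg.align_alleles(geno, stats)
        assert np.allclose(aligned.dosages, dos)
        assert len(kept) == 3

    def test_flipped_snp_complemented(self):
        geno = make_genotypes([[0.0], [1.0], [2.0]], counted=["G"], alt=["A"])
        stats = stats_frame(["rs0"])  # effect allele A
        aligned, _ = pg.align_alleles(geno, stats)
        assert aligned.dosages[:, 0].tolist() == [2.0, 1.0, 0.0]
        assert aligned.counted_allele[0] == "A"

    def test_allele_mismatch_errors(self):
        geno = make_genotypes([[1.0]], counted=["C"], alt=["T"])
        stats = stats_frame(["rs0"], a1="A", a2="G")
        with pytest.raises(ValueError, match="rs0"):
            pg.align_alleles(geno, stats)

    def test_palindromic_dropped_in_strict_mode(self):
        geno = make_genotypes([[1.0, 1.0]], counted=["A", "A"],
                              alt=["T", "G"])
        stats = pd.DataFrame(
            {
                "snp_id": ["rs0", "rs1"],
                "effect_allele": ["A", "A"],
                "other_allele": ["T", "G"],
                "odds_ratio": [1.1, 1.1],
                "p_value": [0.1, 0.1],
            }
        )
        aligned, kept = pg.align_alleles(geno, stats, strict=True)
        assert list(aligned.snp_ids) == ["rs1"]
        assert list(kept["snp_id"]) == ["rs1"]
        aligned2, kept2 = pg.align_alleles(geno, stats, strict=False)
        assert list(aligned2.snp_ids) == ["rs0", "rs1"]

    def test_mixed_file_matches_per_record_oracle(self, rng):
        m = 8
        dos = rng.binomial(2, 0.4, (30, m)).astype(float)
        flip = rng.random(m) < 0.5
        counted = np.where(flip, "G", "A").tolist()
        alt = np.where(flip, "A", "G").tolist()
        geno = make_genotypes(dos, counted=counted, alt=alt)
        stats = stats_frame(list(geno.snp_ids))  # effect A, other G
        aligned, _ = pg.align_alleles(geno, stats)
        for j in range(m):
            expected = 2 - dos[:, j] if flip[j] else dos[:, j]
            assert np.allclose(aligned.dosages[:, j], expected)


class TestComputeScores:
    def test_unit_odds_ratios_give_zero_scores(self, rng):
        dos = rng.binomial(2, 0.3, (10, 4)).astype(float)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids), ors=[1.0] * 4)
        scores = pg.compute_scores(geno, stats)
        assert np.allclose(scores.score, 0.0)
        assert scores.n_snps_used == 4

    def test_pencil_and_paper_two_by_three(self):
        geno = make_genotypes([[0, 1, 2], [2, 0, 1]])
        stats = stats_frame(list(geno.snp_ids), ors=[1.2, 0.8, 1.5])
        scores = pg.compute_scores(geno, stats)
        w = [math.log(1.2), math.log(0.8), math.log(1.5)]
        assert scores.score[0] == pytest.approx((0 * w[0] + 1 * w[1] + 2 * w[2]) / 3)
        assert scores.score[1] == pytest.approx((2 * w[0] + 0 * w[1] + 1 * w[2]) / 3)

    def test_snp_order_invariance(self, rng):
        dos = rng.binomial(2, 0.3, (15, 5)).astype(float)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids), ors=rng.uniform(0.8, 1.3, 5))
        perm = stats.sample(frac=1, random_state=1)
        s1 = pg.compute_scores(geno, stats)
        s2 = pg.compute_scores(geno, perm)
        assert np.allclose(s1.score, s2.score)

    def test_missing_mean_imputation(self):
        dos = np.array([[0.0, 1.0], [2.0, 0.0], [np.nan, 2.0]])
        geno = make_genotypes(dos)
        stats = stats_frame(["rs0", "rs1"], ors=[math.e, math.e])  # weights 1
        scores = pg.compute_scores(geno, stats, missing="mean")
        # missing call imputed to the column mean dosage (0+2)/2 = 1
        assert scores.score[2] == pytest.approx((1.0 + 2.0) / 2)
        complete = pg.compute_scores(geno, stats, missing="complete")
        # per-sample renormalisation over called SNPs only
        assert np.allclose(complete.score, [0.5, 1.0, 2.0])

    def test_allele_divisor_halves_scores(self, rng):
        dos = rng.binomial(2, 0.3, (10, 3)).astype(float)
        geno = make_genotypes(dos)
        stats = stats_frame(list(geno.snp_ids), ors=[1.2, 1.1, 0.9])
        per_snp = pg.compute_scores(geno, stats, divisor="n_snps")
        per_allele = pg.compute_scores(geno, stats, divisor="n_alleles")
        assert np.allclose(per_allele.score, per_snp.score / 2)

    def test_unaligned_genotypes_rejected(self):
        geno = make_genotypes([[1.0]], counted=["G"], alt=["A"])
        stats = stats_frame(["rs0"])
        with pytest.raises(ValueError, match="not aligned"):
            pg.compute_scores(geno, stats)

    def test_label_flip_with_inverted_or_preserves_correlations(self, rng):
        # flipping a SNP's allele labels and inverting its OR shifts every
        # sample's score by the same constant, so phenotype correlations
        # are untouched
        n, m = 60, 5
        dos = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_genotypes(dos)
        ors = rng.uniform(0.8, 1.3, m)
        stats = stats_frame(list(geno.snp_ids), ors=ors)
        pheno = rng.normal(size=n)

        flipped_dos = dos.copy()
        flipped_dos[:, 0] = 2 - flipped_dos[:, 0]
        geno_f = make_genotypes(flipped_dos, counted=["G", "A", "A", "A", "A"],
                                alt=["A", "G", "G", "G", "G"])
        stats_f = stats.copy()
        stats_f.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        stats_f.loc[0, "odds_ratio"] = 1 / ors[0]

        s1 = pg.compute_scores(geno, stats).score
        s2 = pg.compute_scores(geno_f, stats_f).score
        assert np.allclose(np.diff(s1 - s2), 0.0, atol=1e-12)
        assert pearson_r(s1, pheno) == pytest.approx(
            pearson_r(s2, pheno), rel=1e-9
        )


class TestGenotypeIO:
    def test_dosage_tsv_roundtrip(self, tmp_path, rng):
        dos = rng.binomial(2, 0.3, (6, 4)).astype(float)
        dos[0, 0] = np.nan
        geno = make_genotypes(dos)
        pg.write_dosage_tsv(geno, tmp_path / "d.tsv", tmp_path / "a.tsv")
        back = pg.read_dosage_tsv(tmp_path / "d.tsv", tmp_path / "a.tsv")
        assert np.allclose(back.dosages, dos, equal_nan=True)
        assert list(back.snp_ids) == list(geno.snp_ids)
        assert list(back.counted_allele) == list(geno.counted_allele)

    def test_read_vcf_alt_counted(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n"
        )
        geno = pg.read_vcf(vcf)
        assert list(geno.sample_ids) == ["s1", "s2", "s3"]
        assert list(geno.snp_ids) == ["rs1", "rs2"]
        assert geno.counted_allele.tolist() == ["G", "T"]  # ALT counted
        assert geno.dosages[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert np.isnan(geno.dosages[1, 1])
        assert geno.dosages[2, 1] == 0.0

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            make_genotypes([[3.0]])
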