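"""Reading, harmonization, genomic control and IVW meta-analysis."""

import gzip

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glyconet import sumstats as ss

HEADER = "snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\tinfo\n"


def _write(tmp_path, rows, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(rows))
    return path


GOOD_ROWS = [
    "rs1\t1\t100\tA\tG\t0.3\t0.2\t0.05\t6.3e-5\t1000\t0.99\n",
    "rs2\t1\t200\tC\tT\t0.5\t-0.1\t0.04\t0.012\t1000\t0.95\n",
    "rs3\t2\t300\tG\tA\t0.7\t0.0\t0.06\t1.0\t1000\t0.91\n",
]


class TestReadSumstats:
    def test_well_formed_file(self, tmp_path):
        records, rejected = ss.read_sumstats(_write(tmp_path, GOOD_ROWS))
        assert len(records) == 3 and len(rejected) == 0

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("rsX\t1\t1\tA\tG\t0.3\t0.2\t0\t0.5\t1000\t0.9\n", "nonpositive standard error"),
            ("rsX\t1\t1\tA\tG\t1.3\t0.2\t0.1\t0.5\t1000\t0.9\n", "allele frequency outside (0,1)"),
            ("rsX\t1\t1\tA\tA\t0.3\t0.2\t0.1\t0.5\t1000\t0.9\n", "identical alleles"),
            ("rsX\t1\t1\tA\tG\t0.3\t0.2\t0.1\t0\t1000\t0.9\n", "p-value outside (0,1]"),
            ("rsX\t1\t1\tAT\tG\t0.3\t0.2\t0.1\t0.5\t1000\t0.9\n", "non-SNV allele"),
        ],
    )
    def test_invalid_rows_rejected_with_reason(self, tmp_path, row, reason):
        records, rejected = ss.read_sumstats(_write(tmp_path, GOOD_ROWS + [row]))
        assert len(records) == 3
        assert rejected["reject_reason"].iloc[0] == reason

    def test_missing_column_is_hard_failure(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\tchr\nrs1\t1\n")
        with pytest.raises(ss.SumStatError, match="pos"):
            ss.read_sumstats(path)

    def test_gzip_round_trip(self, tmp_path):
        plain, _ = ss.read_sumstats(_write(tmp_path, GOOD_ROWS))
        gz = tmp_path / "stats.tsv.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(HEADER + "".join(GOOD_ROWS))
        zipped, _ = ss.read_sumstats(gz)
        pd.testing.assert_frame_equal(plain, zipped)


class TestHarmonize:
    REF = pd.DataFrame({"snp": ["rs1"], "ea": ["A"], "oa": ["G"]})

    def _record(self, ea, oa, beta=0.2, eaf=0.3):
        return pd.DataFrame(
            {"snp": ["rs1"], "ea": [ea], "oa": [oa], "beta": [beta], "eaf": [eaf]}
        )

    def test_already_oriented_unchanged(self):
        out = ss.harmonize_alleles(self._record("A", "G"), self.REF)
        assert out["beta"].iloc[0] == 0.2 and out["eaf"].iloc[0] == 0.3

    def test_swapped_alleles_flip_beta_and_eaf(self):
        out = ss.harmonize_alleles(self._record("G", "A"), self.REF)
        assert out["beta"].iloc[0] == -0.2
        assert out["eaf"].iloc[0] == pytest.approx(0.7)
        assert out["ea"].iloc[0] == "A" and out["oa"].iloc[0] == "G"

    def test_strand_flip_resolved(self):
        # T/C complements to A/G: direct after complementing
        out = ss.harmonize_alleles(self._record("T", "C"), self.REF)
        assert out["beta"].iloc[0] == 0.2 and out["ea"].iloc[0] == "A"
        # C/T complements to G/A: swap after complementing
        out = ss.harmonize_alleles(self._record("C", "T"), self.REF)
        assert out["beta"].iloc[0] == -0.2

    def test_palindromic_flagged_and_retained(self):
        ref = pd.DataFrame({"snp": ["rs1"], "ea": ["A"], "oa": ["T"]})
        out = ss.harmonize_alleles(self._record("A", "T"), ref)
        assert out["palindromic"].iloc[0]
        assert len(out) == 1
        dropped = ss.harmonize_alleles(self._record("A", "T"), ref, drop_palindromic=True)
        assert len(dropped) == 0

    def test_irreconcilable_alleles_rejected(self):
        with pytest.raises(ss.SumStatError, match="allele mismatch"):
            ss.harmonize_alleles(self._record("A", "C"), self.REF)


class TestGenomicControl:
    def test_lambda_of_constructed_median(self):
        z = np.full(200, np.sqrt(ss.CHI2_1_MEDIAN))
        assert ss.gc_lambda(z=z).lambda_gc == pytest.approx(1.0)

    def test_lambda_all_z_one(self):
        report = ss.gc_lambda(z=np.ones(500))
        assert report.lambda_gc == pytest.approx(1.0 / 0.4549364, rel=1e-5)
        assert report.n_snps_used == 500

    def test_lambda_null_simulation(self, rng):
        z = rng.standard_normal(1_000_000)
        assert 0.99 <= ss.gc_lambda(z=z).lambda_gc <= 1.01

    def test_lambda_floor(self):
        with pytest.raises(ss.SumStatError, match="insufficient SNPs"):
            ss.gc_lambda(z=np.ones(10))

    def test_correct_identity_at_lambda_one(self):
        df = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.045]})
        out = ss.gc_correct(df, 1.0)
        pd.testing.assert_frame_equal(out, df)

    def test_correct_halves_z_at_lambda_four(self):
        df = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.045]})
        out = ss.gc_correct(df, 4.0)
        z = out["beta"] / out["se"]
        assert z.iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(1.0))

    def test_deflation_not_applied_below_one(self):
        df = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.045]})
        out = ss.gc_correct(df, 0.95)
        assert out["se"].iloc[0] == 0.1
        assert out.attrs["lambda_gc"] == 0.95

    def test_idempotent_once_deflated(self):
        df = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.045]})
        once = ss.gc_correct(df, 2.0)
        again = ss.gc_correct(once, 1.0)
        pd.testing.assert_frame_equal(once, again)


def _cohort_frame(betas, ses, snp="rs1", trait="IGP1"):
    k = len(betas)
    return pd.DataFrame(
        {
            "snp": [snp] * k,
            "trait_id": [trait] * k,
            "cohort_id": [f"c{i}" for i in range(k)],
            "ea": ["A"] * k,
            "oa": ["G"] * k,
            "eaf": [0.3] * k,
            "beta": betas,
            "se": ses,
            "n": [1000] * k,
        }
    )


class TestIVWMeta:
    def test_single_cohort_identity(self):
        rec = ss.ivw_meta(_cohort_frame([0.2], [0.05]))
        assert rec["beta"] == pytest.approx(0.2)
        assert rec["se"] == pytest.approx(0.05)

    def test_two_cohort_hand_example(self):
        rec = ss.ivw_meta(_cohort_frame([0.1, 0.3], [0.05, 0.1]))
        # w = 400 and 100: pooled beta (400*0.1+100*0.3)/500 = 0.14
        assert rec["beta"] == pytest.approx(0.14)
        assert rec["se"] == pytest.approx(1 / np.sqrt(500))
        assert rec["direction"] == "++"

    def test_identical_cohorts_shrink_se_by_sqrt2(self):
        rec = ss.ivw_meta(_cohort_frame([0.2, 0.2], [0.05, 0.05]))
        assert rec["beta"] == pytest.approx(0.2)
        assert rec["se"] == pytest.approx(0.05 / np.sqrt(2))

    def test_orientation_mismatch_rejected(self):
        df = _cohort_frame([0.1, 0.3], [0.05, 0.1])
        df.loc[1, ["ea", "oa"]] = ["G", "A"]
        with pytest.raises(ss.SumStatError, match="harmonize"):
            ss.ivw_meta(df)

    def test_vectorized_meta_matches_per_group(self, small_sim):
        meta = small_sim["meta"]
        block = small_sim["sumstats"]
        pick = meta.sample(5, random_state=0)
        for _, row in pick.iterrows():
            sub = block.loc[
                (block["snp"] == row["snp"]) & (block["trait_id"] == row["trait_id"])
            ]
            rec = ss.ivw_meta(sub)
            assert rec["beta"] == pytest.approx(row["beta"], abs=1e-12)
            assert rec["se"] == pytest.approx(row["se"], abs=1e-12)
            assert rec["direction"] == row["direction"]

    def test_row_order_invariance(self, small_sim):
        """Two analyses of the same shuffled inputs agree exactly."""
        stats_df = small_sim["sumstats"]
        shuffled = stats_df.sample(frac=1.0, random_state=7)
        a = ss.meta_analyze(stats_df).sort_values(["snp", "trait_id"]).reset_index(drop=True)
        b = ss.meta_analyze(shuffled).sort_values(["snp", "trait_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_harmonize_then_meta_reference_invariance(self):
        """Pooled |beta| must not depend on which cohort sets the orientation."""
        df = _cohort_frame([0.1, -0.3], [0.05, 0.1])
        df.loc[1, ["ea", "oa"]] = ["G", "A"]
        df.loc[1, "eaf"] = 0.7
        ref_a = pd.DataFrame({"snp": ["rs1"], "ea": ["A"], "oa": ["G"]})
        ref_b = pd.DataFrame({"snp": ["rs1"], "ea": ["G"], "oa": ["A"]})
        rec_a = ss.ivw_meta(ss.harmonize_alleles(df, ref_a))
        rec_b = ss.ivw_meta(ss.harmonize_alleles(df, ref_b))
        assert rec_a["beta"] == pytest.approx(-rec_b["beta"])
        assert rec_a["se"] == pytest.approx(rec_b["se"])
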