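"""Tests of summary-statistic QC, harmonization and IVW meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mzvqtl.association import _slope_p
from mzvqtl.qcmeta import (
    SUMSTAT_COLUMNS,
    availability_filter,
    genome_wide_hits,
    ivw_meta,
    lambda_median,
    qc_summary_stats,
)


def _row(pos, A1="A", A2="G", eaf=0.3, beta=0.1, se=0.05, p=0.05, n=1000, info=0.9):
    return {
        "snp": f"1:{pos}:{A1}:{A2}", "chr": "1", "pos": pos, "A1": A1, "A2": A2,
        "eaf": eaf, "beta": beta, "se": se, "p": p, "n": n, "info": info,
    }


def _ref(rows):
    return pd.DataFrame(rows, columns=["chr", "pos", "ref_A1", "ref_A2", "ref_eaf"])


class TestQC:
    def test_each_rule_fires_once_on_toy_table(self):
        stats_table = pd.DataFrame(
            [
                _row(100),
                _row(200, A1="T", A2="C", beta=0.2),
                _row(300, eaf=0.005),
                _row(400, info=0.4),
                _row(500, A1="AT", A2="A"),
                _row(600, A1="A", A2="G"),
            ]
        )
        ref = _ref(
            [
                ("1", 100, "A", "G", 0.3),
                ("1", 200, "T", "C", 0.3),
                ("1", 300, "A", "G", 0.3),
                ("1", 400, "A", "G", 0.3),
                ("1", 500, "A", "G", 0.3),
                ("1", 600, "A", "C", 0.3),
            ]
        )
        out, report = qc_summary_stats(stats_table, ref)
        assert len(out) == 2
        assert report["low_maf"] == 1
        assert report["low_info"] == 1
        assert report["indels"] == 1
        assert report["allele_mismatch_or_ambiguous"] == 1
        assert report["missing_values"] == 0
        assert report["duplicate_position"] == 0

    def test_swapped_alleles_flip_beta_and_complement_eaf(self):
        stats_table = pd.DataFrame([_row(100, A1="G", A2="A", eaf=0.7, beta=0.1)])
        ref = _ref([("1", 100, "A", "G", 0.3)])
        out, _ = qc_summary_stats(stats_table, ref)
        assert out.loc[0, "beta"] == pytest.approx(-0.1)
        assert out.loc[0, "eaf"] == pytest.approx(0.3)
        assert out.loc[0, "A1"] == "A" and out.loc[0, "A2"] == "G"

    def test_strand_flip_resolved_by_complement(self):
        stats_table = pd.DataFrame([_row(100, A1="T", A2="C", eaf=0.3, beta=0.1)])
        ref = _ref([("1", 100, "A", "G", 0.3)])
        out, _ = qc_summary_stats(stats_table, ref)
        assert len(out) == 1
        assert out.loc[0, "beta"] == pytest.approx(0.1)

    def test_ambiguous_palindromic_dropped_decisive_kept(self):
        stats_table = pd.DataFrame(
            [
                _row(100, A1="A", A2="T", eaf=0.5),         # ambiguous frequency
                _row(200, A1="A", A2="T", eaf=0.1),          # decisive, same side
                _row(300, A1="C", A2="G", eaf=0.9, beta=0.2)  # decisive, other side
            ]
        )
        ref = _ref(
            [("1", 100, "A", "T", 0.5), ("1", 200, "A", "T", 0.1), ("1", 300, "C", "G", 0.1)]
        )
        out, report = qc_summary_stats(stats_table, ref)
        assert report["allele_mismatch_or_ambiguous"] == 1
        kept = out.set_index("pos")
        assert kept.loc[200, "beta"] == pytest.approx(0.1)
        assert kept.loc[300, "beta"] == pytest.approx(-0.2)
        assert kept.loc[300, "eaf"] == pytest.approx(0.1)

    def test_duplicate_positions_keep_largest_sample(self):
        stats_table = pd.DataFrame([_row(100, n=500), _row(100, n=2000, beta=0.7)])
        ref = _ref([("1", 100, "A", "G", 0.3)])
        out, report = qc_summary_stats(stats_table, ref)
        assert report["duplicate_position"] == 1
        assert out.loc[0, "n"] == 2000

    def test_qc_is_idempotent(self):
        rng = np.random.default_rng(12)
        n = 200
        bases = np.array(list("ACGT"))
        ref_rows, stat_rows = [], []
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for i in range(n):
            a1, a2 = rng.choice(bases, 2, replace=False)
            eaf = rng.uniform(0.05, 0.95)
            ref_rows.append(("1", 1000 + i, a1, a2, eaf))
            orient = rng.integers(0, 4)
            b = rng.normal(0, 0.1)
            if orient == 0:
                row = _row(1000 + i, a1, a2, eaf, beta=b)
            elif orient == 1:
                row = _row(1000 + i, a2, a1, 1 - eaf, beta=-b)
            elif orient == 2:
                row = _row(1000 + i, comp[a1], comp[a2], eaf, beta=b)
            else:
                row = _row(1000 + i, comp[a2], comp[a1], 1 - eaf, beta=-b)
            stat_rows.append(row)
        ref = _ref(ref_rows)
        first, rep1 = qc_summary_stats(pd.DataFrame(stat_rows), ref)
        second, rep2 = qc_summary_stats(first, ref)
        pd.testing.assert_frame_equal(first, second)
        removal_rules = [k for k in rep2 if k not in ("input", "output")]
        assert all(rep2[r] == 0 for r in removal_rules)

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="se"):
            qc_summary_stats(pd.DataFrame({"snp": []}), _ref([]))


class TestLambdaMedian:
    def test_half_gives_exactly_one(self):
        assert lambda_median(np.array([0.5])) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_p_values_give_unity(self):
        rng = np.random.default_rng(1)
        assert lambda_median(rng.uniform(size=100_000)) == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance_on_inflated_statistics(self):
        rng = np.random.default_rng(2)
        x = 1.3 * rng.chisquare(1, size=100_000)
        p = stats.chi2.sf(x, 1)
        lam = lambda_median(p)
        oracle = np.median(x) / stats.chi2.ppf(0.5, 1)
        assert lam == pytest.approx(oracle, rel=1e-9)
        assert lam == pytest.approx(1.3, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lambda_median(np.array([]))


def _study(snps, betas, ses, ns=None, eafs=None):
    k = len(snps)
    return pd.DataFrame(
        {
            "snp": snps, "chr": "1", "pos": range(k), "A1": "A", "A2": "G",
            "eaf": eafs if eafs is not None else [0.3] * k,
            "beta": betas, "se": ses,
            "p": [2 * stats.norm.sf(abs(b / s)) for b, s in zip(betas, ses)],
            "n": ns if ns is not None else [1000] * k, "info": 1.0,
        }
    )


class TestIVWMeta:
    def test_single_study_identity(self):
        s = _study(["a", "b"], [0.1, -0.2], [0.05, 0.1])
        meta = ivw_meta([s]).set_index("snp")
        assert meta.loc["a", "beta"] == pytest.approx(0.1)
        assert meta.loc["a", "se"] == pytest.approx(0.05)
        assert meta.loc["a", "p"] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_equal_weight_symmetry(self):
        a = _study(["x"], [0.1], [0.1])
        b = _study(["x"], [0.3], [0.1])
        meta = ivw_meta([a, b])
        assert meta.loc[0, "beta"] == pytest.approx(0.2)
        assert meta.loc[0, "se"] == pytest.approx(0.1 / np.sqrt(2))
        assert meta.loc[0, "direction"] == "++"

    def test_self_meta_halves_variance(self):
        s = _study(["x"], [0.15], [0.07])
        meta = ivw_meta([s, s])
        assert meta.loc[0, "se"] == pytest.approx(0.07 / np.sqrt(2))
        assert meta.loc[0, "beta"] == pytest.approx(0.15)

    def test_study_order_only_permutes_direction(self):
        a = _study(["x", "y"], [0.1, -0.1], [0.1, 0.1])
        b = _study(["x"], [0.3], [0.2])
        m1 = ivw_meta([a, b]).set_index("snp")
        m2 = ivw_meta([b, a]).set_index("snp")
        assert m1.loc["x", "beta"] == pytest.approx(m2.loc["x", "beta"])
        assert m1.loc["x", "direction"] == "++"
        assert m2.loc["x", "direction"] == "++"
        assert m1.loc["y", "direction"] == "-?"
        assert m2.loc["y", "direction"] == "?-"

    def test_missing_study_marked_question(self):
        a = _study(["x", "y"], [0.1, 0.2], [0.1, 0.1])
        b = _study(["x"], [0.1], [0.1])
        meta = ivw_meta([a, b]).set_index("snp")
        assert meta.loc["y", "direction"] == "+?"
        assert meta.loc["y", "n_studies"] == 1

    def test_meta_beats_single_studies_in_mse(self):
        # oracle: pooled regression over the concatenated raw data
        rng = np.random.default_rng(9)
        true = 0.3
        reps, k, n = 300, 5, 100
        err_meta, err_pooled = [], []
        err_single = [[] for _ in range(k)]
        for _ in range(reps):
            studies, all_x, all_y = [], [], []
            for i in range(k):
                x = rng.binomial(2, 0.3, n).astype(float)
                y = true * x + rng.normal(size=n)
                beta, se, _ = _slope_p(x, y)
                studies.append(_study([f"s"], [beta], [se]))
                err_single[i].append((beta - true) ** 2)
                all_x.append(x)
                all_y.append(y)
            meta = ivw_meta(studies)
            err_meta.append((meta.loc[0, "beta"] - true) ** 2)
            bp, _, _ = _slope_p(np.concatenate(all_x), np.concatenate(all_y))
            err_pooled.append((bp - true) ** 2)
        mse_meta = np.mean(err_meta)
        assert all(mse_meta < np.mean(e) for e in err_single)
        assert mse_meta == pytest.approx(np.mean(err_pooled), rel=0.2)

    def test_conflicting_alleles_dropped(self):
        a = _study(["x", "y"], [0.1, 0.2], [0.1, 0.1])
        b = _study(["x", "y"], [0.1, 0.2], [0.1, 0.1])
        b.loc[1, "A1"] = "T"
        meta = ivw_meta([a, b])
        assert set(meta["snp"]) == {"x"}


class TestPostMetaFilters:
    @staticmethod
    def _meta(directions, ps=None):
        k = len(directions)
        return pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(k)],
                "p": ps if ps is not None else [0.5] * k,
                "direction": directions,
            }
        )

    def test_half_available_kept(self):
        out = availability_filter(self._meta(["+++??"]))
        assert len(out) == 1

    def test_mostly_missing_dropped(self):
        out = availability_filter(self._meta(["+????"]))
        assert len(out) == 0

    def test_zero_threshold_is_identity(self):
        meta = self._meta(["+????", "?????"])
        assert len(availability_filter(meta, min_prop=0.0)) == 2

    def test_hits_empty_when_nothing_significant(self):
        assert genome_wide_hits(self._meta(["++"], ps=[0.5])).empty

    def test_hit_below_threshold_returned_sorted(self):
        meta = self._meta(["++", "++", "++"], ps=[9.93e-9, 0.5, 4e-9])
        out = genome_wide_hits(meta)
        assert list(out["p"]) == [4e-9, 9.93e-9]

    def test_threshold_one_returns_everything(self):
        meta = self._meta(["++", "++"], ps=[0.9, 0.2])
        assert len(genome_wide_hits(meta, threshold=1.1)) == 2
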