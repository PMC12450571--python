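import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from miraudit import expression_audit as ea
from miraudit.errors import ValidationError
from miraudit.io_formats import ExpressionMatrix

from conftest import make_cpm_matrix


class TestCountsToCpm:
    def test_closed_form(self):
        out = ea.counts_to_cpm(np.array([1.0, 1.0, 2.0]))
        assert out.tolist() == [250000.0, 250000.0, 500000.0]

    def test_single_nonzero_takes_the_pool(self):
        assert ea.counts_to_cpm(np.array([0.0, 7.0]))[1] == 1e6

    def test_all_zero_column_names_sample(self):
        with pytest.raises(ValidationError, match="liver_1"):
            ea.counts_to_cpm(np.zeros(3), sample="liver_1")

    def test_200_cpm_is_0p02_percent(self):
        assert ea.cpm_to_fraction(200.0) == 0.0002
        assert ea.cpm_to_percent(200.0) == 0.02

    def test_matrix_conversion_columns_sum_to_1e6(self):
        df = pd.DataFrame({"s1": [3.0, 9.0], "s2": [1.0, 1.0]},
                          index=["a", "b"])
        m = ExpressionMatrix(values=df, unit="counts")
        cpm = ea.matrix_counts_to_cpm(m)
        assert np.allclose(cpm.values.sum(axis=0), 1e6)


class TestClassifyThreshold:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.0, "<=10"),
            (10.0, "<=10"),          # inclusive: 10 fails the 10 cpm threshold
            (10.0001, "(10,100]"),
            (100.0, "(10,100]"),     # "never expressed above 100 cpm"
            (100.5, "(100,1000]"),
            (1000.0, "(100,1000]"),
            (62000.0, ">1000"),      # a top HeLa miRNA is far above threshold
        ],
    )
    def test_inclusive_upper_bounds(self, value, expected):
        assert ea.classify_threshold(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            ea.classify_threshold(-1.0)

    def test_custom_thresholds(self):
        assert ea.classify_threshold(15, thresholds=(20,)) == "<=20"
        with pytest.raises(ValidationError):
            ea.bin_labels((100, 10))

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False))
    def test_bin_agrees_with_direct_comparison(self, x):
        bin_ = ea.classify_threshold(x)
        if x <= 10:
            assert bin_ == "<=10"
        elif x <= 100:
            assert bin_ == "(10,100]"
        elif x <= 1000:
            assert bin_ == "(100,1000]"
        else:
            assert bin_ == ">1000"


def _random_matrices(rng, n_mats=2, max_rows=12, max_cols=6):
    mats = []
    all_ids = [f"m{i}" for i in range(max_rows + 4)]
    for k in range(n_mats):
        n = int(rng.integers(2, max_rows))
        c = int(rng.integers(1, max_cols))
        ids = list(rng.choice(all_ids, size=n, replace=False))
        vals = {f"d{k}s{j}": rng.uniform(0, 5000, size=n) for j in range(c)}
        mats.append(make_cpm_matrix(vals, ids, name=f"ds{k}"))
    return mats


def _brute_force_max(mats):
    best = {}
    for m in mats:
        for mature in m.values.index:
            for col in m.values.columns:
                v = float(m.values.loc[mature, col])
                if mature not in best or v > best[mature][0]:
                    best[mature] = (v, col, m.name)
    return best


class TestMaxExpression:
    def test_single_sample_identity(self):
        m = make_cpm_matrix({"s1": [1.0, 3.0]}, ["a", "b"])
        rec = ea.max_expression([m]).set_index("mature_id")
        assert rec.loc["a", "max_cpm"] == m.values.loc["a", "s1"]
        assert rec.loc["a", "argmax_sample"] == "s1"

    def test_max_across_datasets_with_provenance(self):
        a = make_cpm_matrix({"a1": [50.0, 1e6 - 50]}, ["x", "filler"], name="A")
        b = make_cpm_matrix({"b1": [300.0, 1e6 - 300]}, ["x", "filler"], name="B")
        rec = ea.max_expression([a, b]).set_index("mature_id")
        assert rec.loc["x", "max_cpm"] == 300.0
        assert rec.loc["x", "argmax_dataset"] == "B"

    def test_tie_broken_first_seen(self):
        a = make_cpm_matrix({"a1": [500.0, 1e6 - 500]}, ["x", "f"], name="A")
        b = make_cpm_matrix({"b1": [500.0, 1e6 - 500]}, ["x", "f"], name="B")
        rec = ea.max_expression([a, b]).set_index("mature_id")
        assert rec.loc["x", "argmax_dataset"] == "A"

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            mats = _random_matrices(rng)
            rec = ea.max_expression(mats).set_index("mature_id")
            brute = _brute_force_max(mats)
            assert set(rec.index) == set(brute)
            for mature, (v, col, ds) in brute.items():
                assert rec.loc[mature, "max_cpm"] == pytest.approx(v)
                assert rec.loc[mature, "argmax_sample"] == col
                assert rec.loc[mature, "argmax_dataset"] == ds

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        mats = _random_matrices(rng, n_mats=3)
        rec = ea.max_expression(mats)
        shuffled = []
        for m in mats:
            cols = list(rng.permutation(m.values.columns))
            rows = list(rng.permutation(m.values.index))
            shuffled.append(
                ExpressionMatrix(
                    values=m.values.loc[rows, cols],
                    unit="cpm",
                    sample_meta=m.sample_meta.loc[cols],
                    name=m.name,
                )
            )
        rec2 = ea.max_expression(list(reversed(shuffled)))
        merged = rec.merge(rec2, on="mature_id", suffixes=("_a", "_b"))
        assert (merged["max_cpm_a"] == merged["max_cpm_b"]).all()
        assert (merged["bin_a"] == merged["bin_b"]).all()

    def test_monotone_under_data_accrual(self):
        rng = np.random.default_rng(9)
        mats = _random_matrices(rng, n_mats=3)
        r1 = ea.max_expression(mats[:2]).set_index("mature_id")["max_cpm"]
        r2 = ea.max_expression(mats).set_index("mature_id")["max_cpm"]
        common = r1.index.intersection(r2.index)
        assert (r2.loc[common] >= r1.loc[common] - 1e-9).all()

    def test_annotated_but_absent_flagged_not_detected(self, annotations):
        m = make_cpm_matrix({"s1": [1e6]}, ["miR-A-5p"])
        rec = ea.max_expression([m], annotations).set_index("mature_id")
        assert rec.loc["miR-D-5p", "max_cpm"] == 0.0
        assert bool(rec.loc["miR-D-5p", "not_detected"])
        assert rec.loc["miR-D-5p", "bin"] == "<=10"
        assert not rec.loc["miR-A-5p", "not_detected"]

    def test_counts_matrix_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        m = ExpressionMatrix(values=df, unit="counts")
        with pytest.raises(ValidationError):
            ea.max_expression([m])


class TestLocusAggregate:
    def test_locus_takes_best_arm(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix])
        locus, unmapped = ea.locus_aggregate(rec, annotations)
        li = locus.set_index("locus_id")
        a5 = rec.set_index("mature_id").loc["miR-A-5p", "max_cpm"]
        a3 = rec.set_index("mature_id").loc["miR-A-3p", "max_cpm"]
        assert li.loc["mir-A", "max_cpm"] == max(a5, a3)
        assert unmapped.empty

    def test_single_arm_identity(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix])
        locus, _ = ea.locus_aggregate(rec, annotations)
        li = locus.set_index("locus_id")
        assert li.loc["mir-C", "max_cpm"] == rec.set_index("mature_id").loc[
            "miR-C-3p", "max_cpm"
        ]

    def test_unmapped_reported_not_dropped(self, annotations):
        m = make_cpm_matrix({"s1": [5e5, 5e5]}, ["miR-A-5p", "miR-nobody"])
        rec = ea.max_expression([m])
        locus, unmapped = ea.locus_aggregate(rec, annotations)
        assert list(unmapped["mature_id"]) == ["miR-nobody"]
        assert "miR-nobody" not in set(locus["contributing_mature"])

    def test_multilocus_all_credits_every_parent(self):
        from miraudit.annotation_seed import MirnaAnnotation
        seq = "UAGCAUAGGCUAAAGUUUGCAG"
        anns = [
            MirnaAnnotation("m1", "locus1", "5p", seq),
            MirnaAnnotation("m1", "locus2", "5p", seq),
            MirnaAnnotation("m2", "locus3", "3p", "CCGUAAGGCUAAAGUUUGCAG"),
        ]
        m = make_cpm_matrix({"s1": [600.0, 1e6 - 600]}, ["m1", "m2"])
        rec = ea.max_expression([m])
        locus_all, _ = ea.locus_aggregate(rec, anns, multilocus="all")
        locus_first, _ = ea.locus_aggregate(rec, anns, multilocus="first")
        assert set(locus_all["locus_id"]) == {"locus1", "locus2", "locus3"}
        assert set(locus_first["locus_id"]) == {"locus1", "locus3"}
        flagged = locus_all.set_index("locus_id")["multi_locus_credit"]
        assert bool(flagged.loc["locus1"]) and bool(flagged.loc["locus2"])
        assert not bool(flagged.loc["locus3"])

    def test_group_by_max_oracle(self):
        from miraudit.annotation_seed import MirnaAnnotation
        rng = np.random.default_rng(10)
        seq = "UAGCAUAGGCUAAAGUUUGCAG"
        for _ in range(20):
            n_loci = int(rng.integers(2, 8))
            anns, ids = [], []
            for i in range(n_loci):
                for arm in ("5p", "3p")[: int(rng.integers(1, 3))]:
                    mid = f"L{i}-{arm}"
                    anns.append(MirnaAnnotation(mid, f"L{i}", arm, seq))
                    ids.append(mid)
            vals = {"s1": rng.uniform(0, 2000, size=len(ids))}
            m = make_cpm_matrix(vals, ids)
            rec = ea.max_expression([m])
            locus, _ = ea.locus_aggregate(rec, anns)
            by_max = rec.set_index("mature_id")["max_cpm"]
            for row in locus.itertuples(index=False):
                members = [a.mature_id for a in anns
                           if a.locus_id == row.locus_id]
                assert row.max_cpm == pytest.approx(
                    max(by_max[mm] for mm in members)
                )


class TestCumulativeCounts:
    def test_all_low_saturates_early(self):
        locus = pd.DataFrame({"max_cpm": [5.0, 5.0, 5.0]})
        out = ea.cumulative_locus_counts(locus)
        assert out["n_loci_le"].tolist() == [3, 3, 3, 3]

    def test_none_below_smallest_threshold(self):
        locus = pd.DataFrame({"max_cpm": [50.0, 5000.0]})
        out = ea.cumulative_locus_counts(locus)
        assert out["n_loci_le"].tolist()[0] == 0
        assert out["n_loci_le"].tolist()[-1] == 2

    def test_brute_force_and_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            maxima = rng.uniform(0, 5000, size=int(rng.integers(1, 40)))
            locus = pd.DataFrame({"max_cpm": maxima})
            out = ea.cumulative_locus_counts(locus)
            for row in out.itertuples(index=False):
                assert row.n_loci_le == sum(1 for v in maxima
                                            if v <= row.threshold)
            counts = out["n_loci_le"].tolist()
            assert counts == sorted(counts)
            assert counts[-1] == len(maxima)


class TestStratify:
    def test_simple_arithmetic(self, annotations):
        locus = pd.DataFrame(
            {
                "locus_id": ["mir-A", "mir-B", "mir-C", "mir-D"],
                "max_cpm": [5.0, 8.0, 500.0, 5000.0],
                "bin": ["<=10", "<=10", "(100,1000]", ">1000"],
            }
        )
        from miraudit.annotation_seed import MirnaAnnotation
        seq = "UAGCAUAGGCUAAAGUUUGCAG"
        anns = [MirnaAnnotation(f"m{i}", loc, "5p", seq, taxon_node="NodeZ",
                                taxon_age_mya=100.0)
                for i, loc in enumerate(["mir-A", "mir-B", "mir-C", "mir-D"])]
        out = ea.stratify(locus, anns, key="taxon_node")
        row = out.table.set_index("stratum").loc["NodeZ"]
        assert row["n_loci"] == 4
        assert row["pct <=10"] == 50.0

    def test_percentages_sum_to_100(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix], annotations)
        locus, _ = ea.locus_aggregate(rec, annotations)
        for key in ("mirgenedb_member", "taxon_node"):
            out = ea.stratify(locus, annotations, key=key)
            pct_cols = [c for c in out.table.columns if c.startswith("pct ")]
            sums = out.table[pct_cols].sum(axis=1)
            assert np.allclose(sums, 100.0)

    def test_taxon_strata_ordered_old_to_young(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix], annotations)
        locus, _ = ea.locus_aggregate(rec, annotations)
        out = ea.stratify(locus, annotations, key="taxon_node")
        strata = list(out.table["stratum"])
        assert strata.index("Bilateria") < strata.index("Primates")
        assert strata.index("Primates") < strata.index("Homo sapiens")

    def test_empty_stratum_omitted_with_note(self, annotations):
        locus = pd.DataFrame(
            {"locus_id": ["mir-A"], "max_cpm": [5.0], "bin": ["<=10"]}
        )
        out = ea.stratify(locus, annotations, key="taxon_node")
        assert "Primates" in out.empty_strata
        assert "Primates" not in set(out.table["stratum"])


class TestLowExpressionList:
    def test_threshold_zero_empty_when_all_positive(self, annotations,
                                                    cpm_matrix):
        rec = ea.max_expression([cpm_matrix])
        out = ea.low_expression_list(rec, annotations, threshold=0.0)
        assert out.empty

    def test_length_matches_bin_counts(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix], annotations)
        out = ea.low_expression_list(rec, annotations, threshold=100.0)
        n_low_bins = rec["bin"].isin(["<=10", "(10,100]"]).sum()
        assert len(out) == n_low_bins
        assert (out["max_cpm"] <= 100.0).all()

    def test_sorted_and_annotated(self, annotations, cpm_matrix):
        rec = ea.max_expression([cpm_matrix], annotations)
        out = ea.low_expression_list(rec, annotations)
        assert out["max_cpm"].is_monotonic_increasing
        row = out.set_index("mature_id")
        assert row.loc["miR-A-5p", "locus_ids"] == "mir-A"
        assert row.loc["miR-A-5p", "drosha_class"] == "good"
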