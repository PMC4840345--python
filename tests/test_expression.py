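import numpy as np
import pandas as pd
import pytest

from exolnc.expression import (
    ExpressionTable,
    SelectionConfig,
    hcl_cluster,
    intersect_enriched,
    pearson_cell_vs_exosome,
    select_enriched,
    select_outlier_mirnas,
    zscores,
)


def table_from(values: dict[str, list[float]], ids=None, kind="lncRNA"):
    frame = pd.DataFrame(values)
    frame.index = ids or [f"f{i}" for i in range(len(frame))]
    return ExpressionTable(frame, kind=kind)


class TestSelectEnriched:
    def test_threshold_straddle(self):
        tab = table_from({"L1": [2.5, 1.5]}, ids=["hi", "lo"])
        assert select_enriched(tab, "L1") == {"hi"}

    def test_fc_and_z_selects_only_extreme_value(self):
        # hand z-check: values mean 2.88, sample sd 3.981; z(10) = 1.79
        tab = table_from({"L1": [10, 1.1, 1.2, 1.0, 1.1]})
        got = select_enriched(
            tab, "L1", SelectionConfig(fc_min=2.0, z_cut=1.5), mode="fc_and_z"
        )
        assert got == {"f0"}

    def test_down_direction(self):
        tab = table_from({"L1": [-2.5, -1.5, 3.0]})
        assert select_enriched(tab, "L1", direction="down") == {"f0"}

    def test_unknown_line_is_error(self):
        tab = table_from({"L1": [2.5]})
        with pytest.raises(KeyError):
            select_enriched(tab, "L9")

    def test_monotone_in_fc_min(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(3, 2, 50)) + 1
        tab = table_from({"L1": vals.tolist()})
        previous = None
        for fc_min in (1.0, 2.0, 3.0, 5.0, 8.0):
            got = select_enriched(tab, "L1", SelectionConfig(fc_min=fc_min))
            if previous is not None:
                assert got <= previous
            previous = got


class TestIntersect:
    def test_disjoint(self):
        common, _ = intersect_enriched({"a": {"x"}, "b": {"y"}})
        assert common == set()

    def test_simple(self):
        common, _ = intersect_enriched({"a": {"A", "B"}, "b": {"B", "C"}, "c": {"B"}})
        assert common == {"B"}

    def test_result_contained_in_every_set_and_regions_partition(self):
        rng = np.random.default_rng(2)
        sets = {
            f"L{i}": set(rng.choice(50, size=rng.integers(5, 30), replace=False).tolist())
            for i in range(4)
        }
        common, regions = intersect_enriched(sets)
        for s in sets.values():
            assert common <= s
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_enriched({"a": {"x"}})


class TestOutlierMirnas:
    def test_single_extreme_value(self):
        # log10 values [0]*9 + [3]: Q1 = Q3 = 0, IQR = 0, fence = 0
        tab = table_from({"L1": [1.0] * 9 + [1000.0]}, kind="miRNA")
        assert select_outlier_mirnas(tab, "L1") == {"f9"}

    def test_all_equal_gives_empty(self):
        tab = table_from({"L1": [10.0] * 6}, kind="miRNA")
        assert select_outlier_mirnas(tab, "L1") == set()

    def test_symmetric_values_give_empty(self):
        # signed log10 = [-2, -1, 0, 1, 2]; fence = 1 + 1.5*2 = 4
        tab = table_from({"L1": [-100.0, -10.0, 1.0, 10.0, 100.0]}, kind="miRNA")
        assert select_outlier_mirnas(tab, "L1") == set()

    def test_too_few_values(self):
        tab = table_from({"L1": [1.0, 2.0, 3.0]}, kind="miRNA")
        with pytest.raises(ValueError, match="too few"):
            select_outlier_mirnas(tab, "L1")

    def test_requires_mirna_table(self):
        tab = table_from({"L1": [1.0] * 5}, kind="lncRNA")
        with pytest.raises(ValueError):
            select_outlier_mirnas(tab, "L1")


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_cell_vs_exosome(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = [1.0, 2.0, 3.0]
        r, _ = pearson_cell_vs_exosome(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(3)
        cov = [[1, 0.9], [0.9, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10000)
        r, p = pearson_cell_vs_exosome(xy[:, 0], xy[:, 1])
        assert abs(r - 0.9) < 0.02
        assert p < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, _ = pearson_cell_vs_exosome(x, y)
        r2, _ = pearson_cell_vs_exosome(3 * x + 7, 0.5 * y - 2)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_cell_vs_exosome([1, 1, 1], [1, 2, 3])


class TestHclCluster:
    def test_nearest_pair_merges_first(self):
        mat = pd.DataFrame([[0.0, 0.1, 10.0]], columns=["a", "b", "c"])
        res = hcl_cluster(mat)
        # first linkage row joins the two original samples 0 and 1
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_identical_samples_merge_at_zero(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        res = hcl_cluster(mat)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_heights_on_a_line(self):
        # points 0, 1, 5, 6: merges at 1, 1 then mean(|0-5|,|0-6|,|1-5|,|1-6|) = 5
        mat = pd.DataFrame([[0.0, 1.0, 5.0, 6.0]], columns=list("abcd"))
        res = hcl_cluster(mat)
        heights = sorted(res.linkage[:, 2].tolist())
        assert heights == pytest.approx([1.0, 1.0, 5.0])
        assert ("(a:1,b:1)" in res.newick) or ("(b:1,a:1)" in res.newick)

    def test_nan_is_error(self):
        with pytest.raises(ValueError):
            hcl_cluster(pd.DataFrame([[0.0, np.nan]], columns=["a", "b"]))


class TestTableValidation:
    def test_values_inside_unit_band_rejected(self):
        with pytest.raises(ValueError, match="signed fold-change"):
            table_from({"L1": [0.5, 2.0]})

    def test_assume_ratios_converts_reciprocals(self):
        frame = pd.DataFrame({"L1": [0.25, 4.0]}, index=["a", "b"])
        tab = ExpressionTable(frame, assume_ratios=True)
        assert tab.frame.loc["a", "L1"] == pytest.approx(-4.0)
        assert tab.frame.loc["b", "L1"] == pytest.approx(4.0)

    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame({"L1": [2.0, 3.0]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionTable(frame)


def test_zscores_standardize():
    rng = np.random.default_rng(5)
    v = rng.normal(3, 7, size=100)
    z = zscores(v)
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=1) - 1) < 1e-9
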