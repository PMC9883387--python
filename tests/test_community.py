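"""Community metrics against hand calculations and independent oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from fermentomics import (
    alpha_diversity,
    bray_curtis,
    fb_ratio,
    log2_fold_change,
    pcoa,
    relative_abundance,
    unweighted_unifrac,
)
from tests.conftest import make_table

rng = np.random.default_rng(20240915)


class TestRelativeAbundance:
    def test_proportionality(self):
        t = make_table({"a": [5], "b": [5], "c": [10]})
        out = relative_abundance(t)
        assert out[["a", "b", "c"]].iloc[0].tolist() == [25.0, 25.0, 50.0]

    def test_single_taxon_is_total(self):
        out = relative_abundance(make_table({"a": [7]}))
        assert out["a"].iloc[0] == 100.0

    def test_rows_close_to_100(self):
        names = [f"otu{i}" for i in range(15)]
        counts = make_table({n: rng.integers(0, 50, 20).tolist() for n in names})
        counts[names[0]] += 1  # guarantee positive totals
        out = relative_abundance(counts)
        vals = out[names]
        assert np.allclose(vals.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            relative_abundance(make_table({"a": [0], "b": [0]}))


class TestFBRatio:
    @pytest.mark.parametrize(
        "firm,bact,expected,flag",
        [(41.5, 25.0, 1.66, False), (50.0, 20.0, 2.5, True), (30.0, 30.0, 1.0, False)],
    )
    def test_ratio_and_dysbiosis_flag(self, firm, bact, expected, flag):
        t = make_table({"Firmicutes": [firm], "Bacteroidetes": [bact]})
        out = fb_ratio(t)
        assert out["fb_ratio"].iloc[0] == pytest.approx(expected)
        assert bool(out["dysbiosis"].iloc[0]) is flag

    def test_zero_bacteroidetes_is_undefined_not_infinite(self):
        out = fb_ratio(make_table({"Firmicutes": [40.0], "Bacteroidetes": [0.0]}))
        assert np.isnan(out["fb_ratio"].iloc[0])
        assert bool(out["undefined"].iloc[0])

    def test_phylum_aggregation(self):
        t = make_table({"Blautia": [30.0], "Roseburia": [20.0], "Bacteroides": [25.0]})
        out = fb_ratio(t, taxonomy={"Blautia": "Firmicutes", "Roseburia": "Firmicutes",
                                    "Bacteroides": "Bacteroidetes"})
        assert out["fb_ratio"].iloc[0] == pytest.approx(2.0)


class TestLog2FoldChange:
    def _pair(self, base, end):
        meta_end = pd.DataFrame({
            "sample_id": ["e1", "e2"], "treatment": ["HBPA", "HBPA"],
            "time_h": [24.0, 24.0], "bio_rep": [1, 2], "tech_rep": [1, 1],
        })
        baseline = make_table({"X": [base, base]})
        endpoint = make_table({"X": [end, end]}, meta=meta_end)
        return endpoint, baseline

    @pytest.mark.parametrize(
        "base,end,expected",
        [
            (0.974, 3.30, 1.76),   # bifidobacterial bloom
            (0.393, 7.88, 4.32),   # B. thetaiotaomicron top shift
            (2.085, 11.90, 2.51),  # Oscillospira surge
            (1.0, 1.0, 0.00),
        ],
    )
    def test_published_worked_examples(self, base, end, expected):
        endpoint, baseline = self._pair(base, end)
        rec = log2_fold_change(endpoint, baseline, letters=False)
        assert rec["log2fc_HBPA"].iloc[0] == pytest.approx(expected, abs=0.01)

    def test_floor_substitution(self):
        endpoint, baseline = self._pair(0.0, 0.004)
        rec = log2_fold_change(endpoint, baseline, floor=0.001, letters=False)
        assert rec["log2fc_HBPA"].iloc[0] == pytest.approx(2.0)

    def test_antisymmetry_above_floor(self):
        endpoint, baseline = self._pair(0.5, 3.5)
        fwd = log2_fold_change(endpoint, baseline, letters=False)["log2fc_HBPA"].iloc[0]
        # swap roles: relabel to keep treatment bookkeeping intact
        e2, b2 = self._pair(3.5, 0.5)
        rev = log2_fold_change(e2, b2, letters=False)["log2fc_HBPA"].iloc[0]
        assert fwd == pytest.approx(-rev)

    def test_missing_baseline_taxon_rejected(self):
        endpoint, baseline = self._pair(1.0, 2.0)
        baseline = baseline.rename(columns={"X": "Y"})
        with pytest.raises(KeyError, match="absent from baseline"):
            log2_fold_change(endpoint, baseline, letters=False)


def brute_alpha(counts: np.ndarray, metric: str) -> float:
    """Independent direct evaluation of the alpha-diversity formulas."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if metric == "observed_otus":
        return len(counts)
    if metric == "chao1":
        f1 = sum(1 for c in counts if c == 1)
        f2 = sum(1 for c in counts if c == 2)
        return len(counts) + f1 * (f1 - 1) / (2 * (f2 + 1))
    if metric == "shannon":
        return -sum((c / n) * math.log(c / n) for c in counts)
    if metric == "simpson":
        return 1 - sum((c / n) ** 2 for c in counts)
    if metric == "goods_coverage":
        return 1 - sum(1 for c in counts if c == 1) / n
    raise AssertionError(metric)


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_richness(self):
        t = make_table({f"t{i}": [25] for i in range(4)})
        assert alpha_diversity(t, "shannon").iloc[0] == pytest.approx(math.log(4))
        assert alpha_diversity(t, "shannon", log_base=2).iloc[0] == pytest.approx(2.0)

    def test_chao1_closed_form(self):
        # S_obs=10, F1=2, F2=1 -> 10 + 2*1/(2*2) = 10.5
        counts = {f"t{i}": [5] for i in range(7)}
        counts.update({"u1": [1], "u2": [1], "d1": [2]})
        assert alpha_diversity(make_table(counts), "chao1").iloc[0] == pytest.approx(10.5)

    def test_single_taxon_simpson_zero(self):
        assert alpha_diversity(make_table({"a": [50]}), "simpson").iloc[0] == 0.0

    def test_no_singletons_full_coverage(self):
        t = make_table({"a": [5], "b": [3]})
        assert alpha_diversity(t, "goods_coverage").iloc[0] == 1.0
        assert alpha_diversity(t, "goods_rarity").iloc[0] == 0.0

    def test_non_integer_rejected_for_count_metrics(self):
        t = make_table({"a": [5.5], "b": [3.2]})
        with pytest.raises(ValueError, match="integer"):
            alpha_diversity(t, "chao1")

    @pytest.mark.parametrize(
        "metric", ["observed_otus", "chao1", "shannon", "simpson", "goods_coverage"]
    )
    def test_oracle_agreement_on_random_tables(self, metric):
        for _ in range(100):
            row = rng.integers(0, 6, size=rng.integers(3, 12))
            if row.sum() == 0:
                row[0] = 1
            t = make_table({f"t{i}": [int(c)] for i, c in enumerate(row)})
            got = alpha_diversity(t, metric).iloc[0]
            assert got == pytest.approx(brute_alpha(row, metric), abs=1e-12)


class TestBrayCurtis:
    def test_hand_example(self):
        t = make_table({"a": [6, 2], "b": [4, 8]})
        d = bray_curtis(t)
        assert d["s0", "s1"] == pytest.approx(0.4)

    def test_metric_properties_on_random_tables(self):
        for _ in range(20):
            vals = rng.integers(0, 20, size=(4, 6)).astype(float)
            vals[:, 0] += 1
            t = make_table({f"t{j}": vals[:, j].tolist() for j in range(6)})
            d = bray_curtis(t)
            m = d.data
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0)
            assert (m >= 0).all() and (m <= 1 + 1e-12).all()

    def test_identical_and_disjoint(self):
        t = make_table({"a": [3, 3, 0], "b": [1, 1, 0], "c": [0, 0, 5]})
        d = bray_curtis(t)
        assert d["s0", "s1"] == pytest.approx(0.0)
        assert d["s0", "s2"] == pytest.approx(1.0)


# --- UniFrac with an exhaustive branch-enumeration oracle -------------------

def random_tree(leaves: list[str], rng: np.random.Generator):
    """Random binary tree as nested tuples: (child, child) or leaf name."""
    if len(leaves) == 1:
        return leaves[0]
    k = int(rng.integers(1, len(leaves)))
    order = list(rng.permutation(leaves))
    return (random_tree(order[:k], rng), random_tree(order[k:], rng))


class TestUnifrac:
    def _table(self, taxa, presence):
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(presence))],
            "treatment": ["HBPA"] * len(presence),
            "time_h": [0.0] * len(presence),
            "bio_rep": [1] * len(presence),
            "tech_rep": [1] * len(presence),
        })
        return make_table({t: [row[j] for row in presence] for j, t in enumerate(taxa)}, meta=meta)

    def test_worked_examples_on_fixed_tree(self):
        newick = io.StringIO("((A:1,B:1):1,(C:1,D:1):1);")
        t = self._table(list("ABCD"), [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0], [1, 1, 0, 0]])
        d = unweighted_unifrac(t, io.StringIO(t0 := newick.getvalue()))
        assert d["s0", "s1"] == pytest.approx(1.0)   # disjoint clades
        assert d["s0", "s2"] == pytest.approx(0.6)   # unique 3 / total 5
        assert d["s0", "s3"] == pytest.approx(0.0)   # identical presence

    def test_missing_taxon_rejected(self):
        t = self._table(["A", "Z"], [[1, 1], [1, 0]])
        with pytest.raises(KeyError, match="missing from tree"):
            unweighted_unifrac(t, io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))

    def test_agrees_with_branch_enumeration_oracle(self):
        local = np.random.default_rng(7)
        taxa = [f"L{i}" for i in range(8)]
        for _ in range(50):
            tree = random_tree(taxa, local)
            # serialize with per-node lengths, tracking them for the oracle
            lengths = {}

            def walk(n):
                ln = round(float(local.uniform(0.1, 2.0)), 3)
                lengths[id(n)] = ln
                if isinstance(n, str):
                    return f"{n}:{ln}"
                return f"({','.join(walk(c) for c in n)}):{ln}"

            newick = f"({','.join(walk(c) for c in tree)});"

            pres_a = {t for t in taxa if local.random() < 0.6} or {taxa[0]}
            pres_b = {t for t in taxa if local.random() < 0.6} or {taxa[1]}

            def enumerate_unifrac(node):
                unique = total = 0.0

                def leafset(n):
                    return {n} if isinstance(n, str) else set().union(*(leafset(c) for c in n))

                def visit(n):
                    nonlocal unique, total
                    leaves = leafset(n)
                    in_a, in_b = bool(leaves & pres_a), bool(leaves & pres_b)
                    if in_a or in_b:
                        total += lengths[id(n)]
                        if in_a != in_b:
                            unique += lengths[id(n)]
                    if not isinstance(n, str):
                        for c in n:
                            visit(c)

                for c in node:
                    visit(c)
                return unique / total

            table = self._table(
                taxa,
                [[1 if t in pres_a else 0 for t in taxa],
                 [1 if t in pres_b else 0 for t in taxa]],
            )
            got = unweighted_unifrac(table, io.StringIO(newick))["s0", "s1"]
            assert got == pytest.approx(enumerate_unifrac(tree), abs=1e-10)


class TestPcoa:
    def test_all_identical_samples_collapse_to_origin(self):
        from skbio import DistanceMatrix
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.warns(UserWarning):
            res = pcoa(d, n_axes=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_equilateral_triangle_distances_reproduced(self):
        from skbio import DistanceMatrix
        d = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(d, n_axes=2)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_planar_points_round_trip(self):
        from skbio import DistanceMatrix
        pts = rng.normal(size=(4, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = pcoa(DistanceMatrix(dist, ids=list("abcd")), n_axes=2)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        coords = res.coordinates.to_numpy()
        got = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        assert np.allclose(got, dist, atol=1e-9)
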