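"""Essentiality, lineage contrasts and co-dependency profiling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codep_evidence import (
    AnalysisConfig,
    cohort_dependency_abundance,
    codependency_profile,
    dependency_abundance_correlation,
    dependent_fraction,
    lineage_contrast,
    scan_lineages,
    summarize_essentiality,
    top_codependents,
)
from codep_evidence.containers import AbundancePanel
from conftest import make_panel, correlated_vector


class TestDependentFraction:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([-1.0, -1.0, -1.0], (1.0, 3, 3)),
            ([-0.5, -0.4], (0.0, 0, 2)),  # boundary score is not dependent
            ([-0.6, -0.5, -0.4, np.nan], (1 / 3, 1, 3)),
        ],
    )
    def test_counting(self, scores, expected):
        panel = make_panel({"G": scores})
        assert dependent_fraction(panel, "G", -0.5) == pytest.approx(expected)

    def test_absent_gene_raises(self):
        panel = make_panel({"G": [-1.0]})
        with pytest.raises(KeyError):
            dependent_fraction(panel, "MISSING", -0.5)

    def test_all_missing_raises(self):
        panel = make_panel({"G": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="non-missing"):
            dependent_fraction(panel, "G", -0.5)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(-0.4, 0.5, size=50)
        panel = make_panel({"G": values})
        shuffled = make_panel({"G": rng.permutation(values)})
        assert dependent_fraction(panel, "G", -0.5) == dependent_fraction(
            shuffled, "G", -0.5
        )


class TestEssentialityCategories:
    def _panel_with_fraction(self, n_dep, n_total):
        values = [-1.0] * n_dep + [0.0] * (n_total - n_dep)
        return make_panel({"G": values})

    @pytest.mark.parametrize(
        "n_dep, n_total, expected",
        [
            (95, 100, "pan"),          # fraction 0.95
            (31, 100, "strong"),       # fraction 0.31, the 30% rule
            (8, 700, "partial"),       # >= 1% of 700 lines
            (3, 700, "rare"),          # 1% of 700 is 7 > 3, but >= 3 dependent lines
            (2, 700, "none"),
        ],
    )
    def test_rule_order(self, n_dep, n_total, expected):
        panel = self._panel_with_fraction(n_dep, n_total)
        table = summarize_essentiality(panel, ["G"])
        assert table.loc[0, "category"] == expected
        assert table.loc[0, "n_dependent"] == n_dep

    def test_empty_gene_list_gives_empty_table(self):
        panel = self._panel_with_fraction(1, 10)
        assert len(summarize_essentiality(panel, [])) == 0


class TestLineageContrast:
    def test_difference_in_means_is_exact(self):
        # in-group mean -0.73, out-group mean -0.43 -> diff 0.30
        in_scores = [-0.73 + d for d in (-0.2, -0.1, 0.0, 0.1, 0.2)]
        out_scores = [-0.43 + d for d in (-0.3, -0.15, 0.0, 0.15, 0.3, 0.05, -0.05)]
        panel = make_panel(
            {"G": in_scores + out_scores},
            lineage={f"CL{i}": ("HN" if i < 5 else "Other") for i in range(12)},
        )
        c = lineage_contrast(panel, "G", "HN")
        assert c.diff == pytest.approx(0.30, abs=1e-12)
        assert c.diff == c.mean_out - c.mean_in

    def test_welch_statistic_matches_hand_formula(self):
        x_in = np.array([-1.0, -0.8, -0.9, -1.1, -0.7])
        x_out = np.array([-0.2, -0.4, -0.3, -0.1, -0.5, -0.25])
        panel = make_panel(
            {"G": list(x_in) + list(x_out)},
            lineage={f"CL{i}": ("L" if i < 5 else "rest") for i in range(11)},
        )
        c = lineage_contrast(panel, "G", "L")
        v1, v2 = x_in.var(ddof=1) / len(x_in), x_out.var(ddof=1) / len(x_out)
        t_expected = (x_in.mean() - x_out.mean()) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (len(x_in) - 1) + v2**2 / (len(x_out) - 1))
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        assert c.t_stat == pytest.approx(t_expected, abs=1e-12)
        assert c.p == pytest.approx(p_expected, rel=1e-10)

    def test_identical_groups_give_null_contrast(self):
        rng = np.random.default_rng(2)
        values = rng.normal(-0.5, 0.2, size=40)
        panel = make_panel(
            {"G": values},
            lineage={f"CL{i}": ("A" if i % 2 else "B") for i in range(40)},
        )
        c = lineage_contrast(panel, "G", "A")
        assert abs(c.diff) < 0.2
        assert c.p > 0.01

    def test_small_lineage_raises_on_direct_call(self):
        panel = make_panel(
            {"G": [-1.0, -0.9, 0.0, 0.1, 0.2, 0.3]},
            lineage={f"CL{i}": ("tiny" if i < 2 else "rest") for i in range(6)},
        )
        with pytest.raises(ValueError, match="min_lineage_size"):
            lineage_contrast(panel, "G", "tiny")


class TestScanLineages:
    def test_q_properties_and_ordering(self, default_bundle):
        dep = default_bundle[0]
        result = scan_lineages(dep, dep.genes[:30])
        table = result.table
        assert (table["q"] >= table["p"] - 1e-15).all()
        assert (table["q"] <= 1.0).all()
        # sorted by q then p
        assert (table["q"].diff().dropna() >= -1e-15).all()
        # q is monotone with the p-order
        by_p = table.sort_values("p")
        assert (by_p["q"].diff().dropna() >= -1e-15).all()

    def test_planted_shift_is_flagged(self):
        from codep_evidence import SimConfig, simulate_panel

        cfg = SimConfig(
            n_genes=40, n_lines=200, n_lineages=4, noise_sd=0.1,
            lineage_effects=[(30, 0, -0.5)], seed=5,
        )
        dep, *_ = simulate_panel(cfg)
        result = scan_lineages(dep, dep.genes)
        hit = result.table[
            (result.table["gene"] == "G0030") & (result.table["lineage"] == "LIN00")
        ]
        assert bool(hit["significant"].iloc[0])

    def test_all_lineages_too_small_raises_with_skip_info(self):
        panel = make_panel(
            {"G": [-1.0, 0.0, 0.1, 0.2]},
            lineage={f"CL{i}": f"L{i}" for i in range(4)},  # every lineage size 1
        )
        with pytest.raises(ValueError, match="no eligible"):
            scan_lineages(panel, ["G"])


class TestCodependency:
    def _toy_panel(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        return x, make_panel(
            {
                "QUERY": x,
                "SAME": x.copy(),
                "ANTI": -x,
                "NOISE": rng.normal(size=30),
                "FLAT": np.zeros(30),
            }
        )

    def test_identical_partner_ranks_first(self):
        _, panel = self._toy_panel()
        profile = codependency_profile(panel, "QUERY")
        assert profile.partners.iloc[0]["gene"] in {"SAME", "ANTI"}
        same = profile.partners.set_index("gene")
        assert same.loc["SAME", "r"] == pytest.approx(1.0)
        assert same.loc["ANTI", "r"] == pytest.approx(-1.0)

    def test_anticorrelated_partner_rank_depends_on_mode(self):
        _, panel = self._toy_panel()
        absolute = codependency_profile(panel, "QUERY", AnalysisConfig(top_k_mode="absolute"))
        positive = codependency_profile(panel, "QUERY", AnalysisConfig(top_k_mode="positive"))
        # tie |r|=1 between ANTI and SAME: lexicographic puts ANTI first
        assert list(absolute.partners["gene"][:2]) == ["ANTI", "SAME"]
        assert positive.partners.iloc[-1]["gene"] == "ANTI"

    def test_constant_partner_omitted(self):
        _, panel = self._toy_panel()
        profile = codependency_profile(panel, "QUERY")
        assert "FLAT" not in set(profile.partners["gene"])

    def test_constant_query_raises(self):
        _, panel = self._toy_panel()
        with pytest.raises(ValueError, match="constant"):
            codependency_profile(panel, "FLAT")

    def test_r_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 3.5, 0.5, 2.2, 5.0, 1.1, 3.3, 0.1])
        y = np.array([0.9, 2.5, 3.1, 4.0, 1.0, 1.8, 4.4, 1.6, 2.2, 0.4])
        panel = make_panel({"X": x, "Y": y})
        profile = codependency_profile(
            panel, "X", AnalysisConfig(min_codep_overlap=3)
        )
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / (np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2)))
        )
        assert profile.partners.iloc[0]["r"] == pytest.approx(expected, abs=1e-12)

    def test_min_overlap_excludes_sparse_partner(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        sparse = rng.normal(size=20)
        sparse[:12] = np.nan  # only 8 shared lines
        panel = make_panel({"Q": x, "SPARSE": sparse, "DENSE": rng.normal(size=20)})
        profile = codependency_profile(panel, "Q", AnalysisConfig(min_codep_overlap=10))
        assert set(profile.partners["gene"]) == {"DENSE"}

    def test_topk_matches_bruteforce_sort(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(60, 30))
        values[rng.random(values.shape) < 0.05] = np.nan
        panel = make_panel({f"G{j:02d}": values[:, j] for j in range(30)})
        cfg = AnalysisConfig(min_codep_overlap=10)
        profile = codependency_profile(panel, "G00", cfg)
        # naive double loop over pairwise-complete supports
        brute = []
        x = values[:, 0]
        for j in range(1, 30):
            y = values[:, j]
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 10:
                continue
            xs, ys = x[mask], y[mask]
            if xs.std() == 0 or ys.std() == 0:
                continue
            brute.append((f"G{j:02d}", float(np.corrcoef(xs, ys)[0, 1])))
        brute.sort(key=lambda t: (-abs(t[1]), t[0]))
        top = top_codependents(profile, 7)
        assert [g for g, _, _ in top] == [g for g, _ in brute[:7]]
        for (g1, r1, _), (g2, r2) in zip(top, brute[:7]):
            assert r1 == pytest.approx(r2, abs=1e-12)


class TestTopCodependents:
    def _profile(self, pairs):
        df = pd.DataFrame(pairs, columns=["gene", "r", "n"])
        from codep_evidence import CodependencyProfile

        return CodependencyProfile(query="Q", partners=df)

    def test_truncates_to_seven(self):
        profile = self._profile([(f"G{i}", 0.9 - 0.05 * i, 50) for i in range(10)])
        assert len(top_codependents(profile, 7)) == 7

    def test_short_profile_returned_whole(self):
        profile = self._profile([("A", 0.9, 50), ("B", 0.8, 50), ("C", 0.7, 50)])
        assert len(top_codependents(profile, 7)) == 3

    def test_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        yb = correlated_vector(x, 0.5)
        panel = make_panel({"Q": x, "B": yb, "A": yb.copy()})
        profile = codependency_profile(panel, "Q", AnalysisConfig(min_codep_overlap=3))
        top = top_codependents(profile, 2)
        assert [g for g, _, _ in top] == ["A", "B"]


class TestDependencyAbundance:
    def _panels(self, x, y):
        dep = make_panel({"G": x})
        ab = AbundancePanel(
            abundance=pd.DataFrame(
                [y], index=["G"], columns=[f"CL{i}" for i in range(len(y))]
            )
        )
        return dep, ab

    def test_affine_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        dep, ab = self._panels(x, 2.5 * x + 1.0)
        r, p, n = dependency_abundance_correlation(dep, ab, "G")
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_p_matches_t_distribution_closed_form(self):
        x = np.array([0.1, 0.4, -0.2, 0.9, -0.5])
        y = np.array([0.3, 0.1, -0.4, 0.7, -0.2])
        dep, ab = self._panels(x, y)
        r, p, n = dependency_abundance_correlation(
            dep, ab, "G", AnalysisConfig(min_codep_overlap=3)
        )
        t = r * math.sqrt((n - 2) / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-12)

    def test_independent_vectors_have_small_r(self):
        rng = np.random.default_rng(8)
        dep, ab = self._panels(rng.normal(size=200), rng.normal(size=200))
        r, _, _ = dependency_abundance_correlation(dep, ab, "G")
        assert abs(r) < 0.2

    def test_insufficient_overlap_is_reason_coded_skip(self):
        x = [0.1, 0.2, 0.3]
        dep, ab = self._panels(x, [np.nan, np.nan, np.nan])
        assert dependency_abundance_correlation(dep, ab, "G") is None
        table, summary = cohort_dependency_abundance(dep, ab, ["G", "ABSENT"])
        assert len(table) == 0
        assert summary["n_skipped"] == 2
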