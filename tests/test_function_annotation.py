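import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirarray import function_annotation as fa
from mirarray.errors import ConfigurationError, InputError


def exact_upper_tail(k, K, n, N) -> Fraction:
    """Exhaustive hypergeometric tail with exact integer arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def term_frame(members_by_term, category="BP"):
    rows = [
        (tid, tid, category, g)
        for tid, members in members_by_term.items()
        for g in members
    ]
    return pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene"])


class TestConsensus:
    tables = {
        "targetscan": {("m1", "G1"), ("m1", "G2"), ("m1", "G3")},
        "miranda": {("m1", "G1"), ("m1", "G2")},
        "mirdb": {("m1", "G1"), ("m1", "G2")},
        "mirwalk": {("m1", "G1")},
    }

    def test_three_of_four_kept_two_dropped(self):
        out = fa.consensus_targets(self.tables, min_support=3)
        assert out == {"m1": {"G1", "G2"}}

    def test_min_support_one_is_the_union(self):
        out = fa.consensus_targets(self.tables, min_support=1)
        assert out == {"m1": {"G1", "G2", "G3"}}

    def test_support_monotonicity(self):
        prev = None
        for s in (4, 3, 2, 1):
            cur = fa.consensus_targets(self.tables, min_support=s)
            pairs = {(m, g) for m, gs in cur.items() for g in gs}
            if prev is not None:
                assert prev <= pairs
            prev = pairs

    def test_symbol_case_normalized(self):
        tables = {
            "a": {("m1", "ABC1")},
            "b": {("m1", "abc1")},
            "c": {("m1", "Abc1")},
            "d": set(),
        }
        assert fa.consensus_targets(tables, 3) == {"m1": {"Abc1"}}

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            fa.consensus_targets(self.tables, min_support=0)
        with pytest.raises(ConfigurationError):
            fa.consensus_targets(self.tables, min_support=5)
        with pytest.raises(InputError):
            fa.consensus_targets({"only": set()}, min_support=1)


class TestTissueFilter:
    spec = {"G1": {"liver", "kidney"}, "G2": {"brain"}, "G3": {"liver"}}

    def test_liver_annotated_kept_others_dropped(self):
        targets = {"m1": {"G1", "G2", "G3", "G4"}}
        kept, report = fa.tissue_filter(targets, self.spec, "liver")
        assert kept == {"m1": {"G1", "G3"}}
        assert report["n_kept"] == 2
        assert report["n_dropped_other_tissue"] == 1
        assert report["n_dropped_unannotated"] == 1

    def test_unknown_tissue_warns_and_empties(self, caplog):
        with caplog.at_level("WARNING", logger="mirarray"):
            kept, report = fa.tissue_filter({"m1": {"G1"}}, self.spec, "lung")
        assert kept == {} and report["n_kept"] == 0
        assert any("lung" in r.message for r in caplog.records)


class TestFisher:
    def test_no_overlap_gives_p_one(self):
        assert fa.hypergeom_upper_tail(0, 5, 5, 20) == 1.0

    def test_complete_overlap_closed_form(self):
        # drawing all 5 marked genes in 5 tries out of 20: 1 / C(20,5)
        p = fa.hypergeom_upper_tail(5, 5, 5, 20)
        assert p == pytest.approx(1 / 15504, rel=1e-12)

    def test_matches_exact_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            p = fa.hypergeom_upper_tail(k, K, n, N)
            exact = float(exact_upper_tail(k, K, n, N))
            assert p == pytest.approx(exact, rel=1e-12)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            table = [[k, n - k], [K - k, N - K - n + k]]
            _, p_sp = stats.fisher_exact(table, alternative="greater")
            assert fa.hypergeom_upper_tail(k, K, n, N) == pytest.approx(p_sp, rel=1e-9)


class TestEnrich:
    genes = [f"G{i:03d}" for i in range(60)]

    def test_selected_equals_universe_degenerate(self):
        terms = term_frame({"T1": self.genes[:10], "T2": self.genes[5:20]})
        rows = fa.enrich(self.genes, self.genes, terms)
        assert (rows["k"] == rows["K"]).all()
        assert (rows["p_value"] == 1.0).all()

    def test_counts_and_chi2_cross_check(self):
        terms = term_frame({"T1": self.genes[:20]})
        rows = fa.enrich(self.genes[:15], self.genes, terms)
        r = rows.iloc[0]
        assert (r["k"], r["K"], r["n"], r["N"]) == (15, 20, 15, 60)
        table = [[r["k"], r["n"] - r["k"]], [r["K"] - r["k"], r["N"] - r["K"] - r["n"] + r["k"]]]
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert r["chi2"] == pytest.approx(chi2)
        assert r["p_chi2"] == pytest.approx(p)

    def test_selected_outside_universe_rejected(self):
        terms = term_frame({"T1": self.genes[:5]})
        with pytest.raises(InputError, match="ZZZ"):
            fa.enrich(["ZZZ"], self.genes, terms)

    def test_term_without_universe_genes_skipped(self, caplog):
        terms = term_frame({"T1": self.genes[:5], "T2": ["NOPE1", "NOPE2"]})
        with caplog.at_level("WARNING", logger="mirarray"):
            rows = fa.enrich(self.genes[:5], self.genes, terms)
        assert rows["term_id"].tolist() == ["T1"]
        assert any("T2" in r.message for r in caplog.records)

    def test_bh_fdr_properties(self):
        rng = np.random.default_rng(12)
        members = {
            f"T{i:02d}": list(rng.choice(self.genes, size=12, replace=False))
            for i in range(15)
        }
        rows = fa.enrich(self.genes[:20], self.genes, term_frame(members))
        assert (rows["fdr"] >= rows["p_value"] - 1e-15).all()
        assert rows["fdr"].max() <= 1.0
        ordered = rows.sort_values("p_value")
        assert ordered["fdr"].is_monotonic_increasing
        # BH oracle: adjusted p = min over j >= i of p_(j) * m / j
        ps = np.sort(rows["p_value"].to_numpy())
        m = len(ps)
        stepup = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(np.sort(rows["fdr"].to_numpy()), np.minimum(stepup, 1.0))

    def test_fdr_within_category(self):
        terms = pd.concat(
            [
                term_frame({"B1": self.genes[:10]}, "BP"),
                term_frame({"P1": self.genes[:10]}, "pathway"),
            ],
            ignore_index=True,
        )
        rows = fa.enrich(self.genes[:10], self.genes, terms).set_index("term_id")
        # identical tables in singleton categories adjust independently
        assert rows.loc["B1", "fdr"] == rows.loc["B1", "p_value"]
        assert rows.loc["P1", "fdr"] == rows.loc["P1", "p_value"]

    def test_ease_deflates_significance(self):
        terms = term_frame({"T1": self.genes[:6]})
        plain = fa.enrich(self.genes[:6], self.genes, terms)
        eased = fa.enrich(self.genes[:6], self.genes, terms, ease=True)
        assert eased["p_value"].iloc[0] > plain["p_value"].iloc[0]


class TestTopTerms:
    def rows(self, entries):
        df = pd.DataFrame(
            entries, columns=["term_id", "category", "k", "p_value", "fdr"]
        )
        df["term_name"] = df["term_id"]
        df["significant"] = (df["p_value"] < 0.05) & (df["fdr"] < 0.05)
        return df

    def test_truncation_and_order(self):
        entries = [(f"T{i}", "BP", 5, 0.001 * (i + 1), 0.01) for i in range(12)]
        top = fa.top_terms(self.rows(entries), k=10)
        assert len(top) == 10
        assert top["p_value"].is_monotonic_increasing

    def test_fewer_significant_than_k(self):
        entries = [("T1", "BP", 5, 0.001, 0.01), ("T2", "BP", 5, 0.5, 0.6)]
        top = fa.top_terms(self.rows(entries), k=10)
        assert top["term_id"].tolist() == ["T1"]

    def test_tie_break_larger_overlap_then_id(self):
        entries = [
            ("T2", "BP", 5, 0.001, 0.01),
            ("T1", "BP", 9, 0.001, 0.01),
            ("T0", "BP", 9, 0.001, 0.01),
        ]
        top = fa.top_terms(self.rows(entries), k=10)
        assert top["term_id"].tolist() == ["T0", "T1", "T2"]
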