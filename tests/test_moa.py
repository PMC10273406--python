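"""tSignal, reverted-protein taxonomy, rank-sum/BH/hypergeometric oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from virtrial.definitions import DiseaseDefinition, Motive, ProteinRef
from virtrial.moa import (
    MoAError,
    bh_fdr,
    differentially_reverted,
    enrich,
    most_strongly_reverted,
    motive_counts,
    parse_gmt,
    reverted_protein_report,
    reverted_proteins,
    tsignal,
    wilcoxon_rank_sum,
)


def two_protein_disease():
    return DiseaseDefinition(
        "toy",
        [
            Motive("neurotransmitter imbalance", [(ProteinRef("A"), 1)]),
            Motive("neuroinflammation", [(ProteinRef("B"), -1)]),
        ],
    )


class TestTSignal:
    def test_zero_activity_gives_zero(self):
        res = tsignal({"A": 0.0, "B": 0.0}, two_protein_disease())
        assert res.value == 0.0

    def test_perfect_reversion_scores_one(self):
        """Disease {A:+1, B:-1} with activities {A:-1, B:+1} is complete
        reversion: sign-adjusted tSignal = 1."""
        res = tsignal({"A": -1.0, "B": 1.0}, two_protein_disease())
        assert res.value == 1.0

    def test_partial_reversion_arithmetic(self):
        res = tsignal({"A": -0.5, "B": 0.0}, two_protein_disease())
        assert res.value == pytest.approx(0.25)
        assert res.per_motive["neurotransmitter imbalance"] == pytest.approx(0.5)
        assert res.per_motive["neuroinflammation"] == pytest.approx(0.0)

    def test_linear_and_permutation_invariant(self, disease):
        rng = np.random.default_rng(0)
        act = {g: float(rng.uniform(-1, 1)) for g in disease.genes()}
        v1 = tsignal(act, disease).value
        half = tsignal({g: v / 2 for g, v in act.items()}, disease).value
        assert half == pytest.approx(v1 / 2)
        shuffled = dict(reversed(list(act.items())))
        assert tsignal(shuffled, disease).value == pytest.approx(v1)
        assert -1.0 <= v1 <= 1.0

    def test_missing_protein_rejected(self):
        with pytest.raises(MoAError):
            tsignal({"A": 0.1}, two_protein_disease())


class TestRevertedProteins:
    def test_threshold_is_strict(self):
        """|activity| exactly 0.5 is NOT reverted (strictly greater rule)."""
        dis = two_protein_disease()
        assert reverted_proteins({"A": -0.5, "B": 0.5}, dis) == set()
        assert reverted_proteins({"A": -0.501, "B": 0.0}, dis) == {"A"}

    def test_direction_must_oppose_disease_sign(self):
        dis = two_protein_disease()
        assert reverted_proteins({"A": -0.8, "B": 0.0}, dis) == {"A"}
        assert reverted_proteins({"A": 0.8, "B": 0.0}, dis) == set()


class TestWilcoxon:
    def test_exact_small_sample_example(self):
        """Fully separated groups of 3: two-sided exact p = 2/C(6,3) = 0.1."""
        p = wilcoxon_rank_sum([0.1, 0.2, 0.3], [0.9, 1.0, 1.1])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 4), (8, 7)])
    def test_matches_enumeration_oracle(self, na, nb):
        """Exact p agrees with brute-force enumeration of all rank splits
        for group sizes <= 8."""
        rng = np.random.default_rng(na * 10 + nb)
        x = rng.normal(0, 1, na)
        y = rng.normal(0.8, 1, nb)
        p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:na].sum()
        mean = na * (len(pooled) + 1) / 2.0
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), na):
            w = ranks[list(combo)].sum()
            if abs(w - mean) >= abs(obs - mean) - 1e-9:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_all_tied_gives_one(self):
        assert wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0


class TestBH:
    def test_single_small_p_among_ones(self):
        """One p = 0.001 among 10 tests adjusts to 0.001 * 10 / 1 = 0.01."""
        fdr = bh_fdr([0.001] + [1.0] * 9)
        assert fdr[0] == pytest.approx(0.01)
        assert np.all(fdr[1:] == 1.0)

    @given(
        st.lists(st.floats(0.0001, 1.0), min_size=2, max_size=10),
        st.integers(0, 9),
    )
    def test_monotone_in_raw_p(self, ps, which):
        """Lowering one raw p never raises any adjusted value."""
        which %= len(ps)
        base = bh_fdr(ps)
        lowered = list(ps)
        lowered[which] = lowered[which] / 2
        low = bh_fdr(lowered)
        assert np.all(low <= base + 1e-12)


class TestDifferentialAndStrong:
    def make_activities(self, values_a, values_b):
        acts_a = [{"A": v, "B": 0.0} for v in values_a]
        acts_b = [{"A": v, "B": 0.0} for v in values_b]
        return acts_a, acts_b

    def test_identical_ensembles_give_nothing_significant(self):
        dis = two_protein_disease()
        a, b = self.make_activities([-0.8, -0.9, -0.7], [-0.8, -0.9, -0.7])
        table = differentially_reverted(a, b, dis)
        assert not table["significant"].any()

    def test_separated_ensembles_detected(self):
        dis = two_protein_disease()
        a, b = self.make_activities(
            [-0.9, -0.85, -0.8, -0.95, -0.7, -0.75], [-0.1, -0.05, 0.0, -0.2, 0.1, 0.05]
        )
        table = differentially_reverted(a, b, dis, alpha=0.05)
        row = table[table["protein"] == "A"].iloc[0]
        assert row["significant"]

    def test_degenerate_protein_reported_with_fdr_one(self):
        dis = two_protein_disease()
        # A reverted (mean -0.9) but identical across drugs -> p = 1 kept in table
        a, b = self.make_activities([-0.9, -0.9, -0.9], [-0.9, -0.9, -0.9])
        table = differentially_reverted(a, b, dis)
        assert list(table["protein"]) == ["A"]
        assert table["fdr"].iloc[0] == 1.0

    def test_most_strongly_matches_threshold_search_oracle(self):
        """Disjoint-range decision agrees with brute-force search over all
        midpoint thresholds on random instances."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            va = rng.normal(rng.uniform(-0.5, 0.5), 0.3, size=6)
            vb = rng.normal(rng.uniform(-0.5, 0.5), 0.3, size=6)
            acts_a = [{"A": float(v)} for v in va]
            acts_b = [{"A": float(v)} for v in vb]
            got = most_strongly_reverted(["A"], acts_a, acts_b)
            pooled = np.sort(np.concatenate([va, vb]))
            mids = (pooled[:-1] + pooled[1:]) / 2
            perfect = any(
                (np.all(va < m) and np.all(vb > m))
                or (np.all(vb < m) and np.all(va > m))
                for m in mids
            )
            assert (got == {"A"}) == perfect

    def test_report_nesting_invariant(self, small_network, disease, ensemble):
        """most_strongly ⊆ differentially ⊆ reverted-by-either on real
        engine output."""
        from virtrial import qsp

        stim_a = {"TAAR1": 1.0, "SLC6A3": -1.0}
        stim_b = {"HTR1A": 1.0, "SLC6A3": -0.5}
        acts_a = [qsp.propagate(s, small_network, stim_a) for s in ensemble.solutions]
        acts_b = [qsp.propagate(s, small_network, stim_b) for s in ensemble.solutions]
        report = reverted_protein_report(acts_a, acts_b, disease)
        sig = set(report.differential.loc[report.differential["significant"], "protein"])
        assert report.most_strongly <= sig
        assert sig <= (report.reverted_a | report.reverted_b)


class TestMotiveCounts:
    def test_counts_with_multiplicity(self):
        dis = DiseaseDefinition(
            "toy",
            [
                Motive("m1", [(ProteinRef("A"), 1), (ProteinRef("B"), 1)]),
                Motive("m2", [(ProteinRef("A"), 1)]),
                Motive("m3", [(ProteinRef("C"), -1)]),
                Motive("m4", [(ProteinRef("D"), -1)]),
            ],
        )
        assert motive_counts(set(), dis) == {"m1": 0, "m2": 0, "m3": 0, "m4": 0}
        assert motive_counts({"B"}, dis)["m1"] == 1
        counts = motive_counts({"A"}, dis)
        assert counts["m1"] == 1 and counts["m2"] == 1


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        """Universe 10, term of 5, query of 3 fully inside: upper-tail
        p = C(5,3)/C(10,3)."""
        universe = {f"P{i}" for i in range(10)}
        term = {f"P{i}" for i in range(5)}
        query = {"P0", "P1", "P2"}
        table = enrich(query, {"t": term}, universe)
        expected = math.comb(5, 3) / math.comb(10, 3)
        assert table["p"].iloc[0] == pytest.approx(expected)
        # single term: BH identity
        assert table["fdr"].iloc[0] == pytest.approx(expected)

    def test_disjoint_query_gives_p_one(self):
        universe = {f"P{i}" for i in range(10)}
        table = enrich({"P9"}, {"t": {f"P{i}" for i in range(5)}}, universe)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(MoAError):
            enrich(set(), {"t": {"A"}}, set())

    def test_gmt_parsing(self):
        terms = parse_gmt("t1\tdesc\tA\tB\nt2\tdesc\tC\n")
        assert terms == {"t1": {"A", "B"}, "t2": {"C"}}
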