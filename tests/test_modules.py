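import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirreg import modules as mod


def brute_hypergeom_tail(r, pop, succ, draws):
    """Exhaustive pmf summation of the upper hypergeometric tail."""
    total = 0.0
    for x in range(r, min(succ, draws) + 1):
        total += (math.comb(succ, x) * math.comb(pop - succ, draws - x)
                  / math.comb(pop, draws))
    return total


def brute_binom_tail(k, n, p):
    return sum(math.comb(n, c) * p**c * (1 - p) ** (n - c)
               for c in range(k, n + 1))


class TestLinkMirnas:
    PWS = {"A": frozenset({"g1", "g2"}), "B": frozenset({"g1", "g3"}),
           "C": frozenset({"g9"})}

    def test_target_in_two_pathways(self):
        linked = mod.link_mirnas_to_pathways({"m1": {"g1"}}, self.PWS)
        assert linked["m1"] == {"A", "B"}

    def test_no_pathway_targets_empty(self):
        linked = mod.link_mirnas_to_pathways({"m1": {"gX"}}, self.PWS)
        assert linked["m1"] == set()

    def test_toy_mapping_hand_derived(self):
        targets = {"m1": {"g1"}, "m2": {"g2", "g3"}, "m3": {"g9", "gZ"}}
        linked = mod.link_mirnas_to_pathways(targets, self.PWS)
        assert linked == {"m1": {"A", "B"}, "m2": {"A", "B"}, "m3": {"C"}}


class TestEnumerateCandidates:
    def test_three_choose_two(self):
        mp = {m: {"w"} for m in "abc"}
        assert mod.enumerate_candidates(mp, 2) == [("a", "b"), ("a", "c"),
                                                   ("b", "c")]

    def test_no_cross_pathway_pairs(self):
        mp = {"a": {"w1"}, "b": {"w1"}, "c": {"w2"}, "d": {"w2"}}
        assert mod.enumerate_candidates(mp, 2) == [("a", "b"), ("c", "d")]

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(0)
        mirnas = [f"m{i}" for i in range(10)]
        pws = [f"w{i}" for i in range(4)]
        mp = {m: {w for w in pws if rng.random() < 0.4} for m in mirnas}
        for k in (1, 2, 3):
            expected = sorted({
                tuple(sorted(sub)) for sub in combinations(mirnas, k)
                if set.intersection(*(mp[m] for m in sub))})
            assert mod.enumerate_candidates(mp, k) == expected

    def test_cap_bounds_combinatorics(self):
        mp = {f"m{i:02d}": {"w"} for i in range(10)}
        capped = mod.enumerate_candidates(mp, 2, per_pathway_cap=4)
        assert len(capped) == math.comb(4, 2)


class TestPathwayEnrichment:
    def test_saturated_population(self):
        assert mod.pathway_enrichment(3, 20, 1.0, 6) == 1.0

    def test_zero_overlap_full_tail(self):
        assert mod.pathway_enrichment(0, 20, 0.25, 6) == 1.0

    def test_matches_enumeration(self):
        # population 20, successes round(0.25*20)=5, draws 6, overlap 3
        expected = brute_hypergeom_tail(3, 20, 5, 6)
        assert mod.pathway_enrichment(3, 20, 0.25, 6) == pytest.approx(
            expected, abs=1e-12)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            mod.pathway_enrichment(5, 20, 0.05, 6)  # successes=1 < r_w=5


class TestBinomialScreens:
    def test_involvement_zero_enriched_is_one(self):
        assert mod.involvement_test(0, 10, 0.1) == 1.0

    def test_involvement_hand_value(self):
        # P(X >= 3), X ~ Binom(10, 0.1) = 1 - sum_{x<=2} pmf = 0.070191
        assert mod.involvement_test(3, 10, 0.1) == pytest.approx(0.0701908,
                                                                 abs=1e-6)

    def test_involvement_impossible_null(self):
        assert mod.involvement_test(1, 10, 0.0) == 0.0

    def test_recurrence_single_tail_term(self):
        assert mod.recurrence_test(4, 4, 0.25) == pytest.approx(0.25**4)

    def test_recurrence_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            d = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert mod.recurrence_test(d, n, p) == pytest.approx(
                brute_binom_tail(d, n, p), abs=1e-12)


class TestFdrControl:
    def test_single_p_identity(self):
        assert mod.fdr_control([0.03])[0] == pytest.approx(0.03)

    def test_hand_bh(self):
        q = mod.fdr_control([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(mod.fdr_control([1.0, 1.0, 1.0]), 1.0)

    def test_step_up_formula_exact(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        q = mod.fdr_control(p)
        order = np.argsort(p)
        m = len(p)
        expected = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        assert np.allclose(q, expected, atol=1e-12)


class TestFindModules:
    def _selections(self):
        """Three conditions; miRNAs a,b jointly cover pathway PW1's genes in
        all three; background miRNAs m1..m4 regulate genes outside any
        pathway (they enlarge the regulated-gene population); miRNA z has
        an unrelated target in one condition only."""
        rows = []
        for cancer, stage in [("C1", "I"), ("C1", "II"), ("C2", "I")]:
            for m, genes in [("a", ["g1", "g2", "g3", "g4"]),
                             ("b", ["g3", "g4", "g5", "g6"])]:
                for g in genes:
                    rows.append((g, cancer, stage, m, "miRNA"))
            for i in range(1, 5):
                for g in (f"h{i}a", f"h{i}b"):
                    rows.append((g, cancer, stage, f"m{i}", "miRNA"))
        rows.append(("g9", "C1", "I", "z", "miRNA"))
        return pd.DataFrame(rows, columns=["gene_id", "cancer_type", "stage",
                                           "regulator_id", "kind"])

    def _pathways(self):
        return {"PW1": frozenset({"g1", "g2", "g3", "g4", "g5", "g6"}),
                "PW2": frozenset({"x1", "x2", "x3", "x4", "x5"})}

    def test_recurrent_pair_reported(self):
        universe = [f"g{i}" for i in range(1, 40)]
        rep = mod.find_modules(self._selections(), self._pathways(), universe,
                               k_min=1, k_max=2)
        assert "a,b" in set(rep.candidates.mirna_set)
        row = rep.candidates[rep.candidates.mirna_set == "a,b"].iloc[0]
        assert row.d_m == 3

    def test_single_condition_candidate_not_reported(self):
        universe = [f"g{i}" for i in range(1, 40)]
        rep = mod.find_modules(self._selections(), self._pathways(), universe,
                               k_min=1, k_max=2)
        # z appears in one condition only; the recurrence floor excludes it
        assert "z" not in set(rep.modules.mirna_set)

    def test_every_reported_mirna_is_pathway_linked(self):
        universe = [f"g{i}" for i in range(1, 40)]
        rep = mod.find_modules(self._selections(), self._pathways(), universe,
                               k_min=1, k_max=2)
        sel = self._selections()
        for _, row in rep.modules.iterrows():
            for cond in row.conditions.split(";"):
                cancer, stage = cond.split("|")
                sub = sel[(sel.cancer_type == cancer) & (sel.stage == stage)]
                for m in row.mirna_set.split(","):
                    targets = set(sub[sub.regulator_id == m].gene_id)
                    assert any(targets & genes
                               for genes in self._pathways().values())

    def test_q_threshold_excludes(self):
        universe = [f"g{i}" for i in range(1, 40)]
        rep = mod.find_modules(self._selections(), self._pathways(), universe,
                               k_min=1, k_max=2, q_threshold=1e-12)
        assert len(rep.modules) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            mod.find_modules(self._selections(), self._pathways(), [])
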