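import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rejuvenet.synth import SimSpec, make_planted_trn
from rejuvenet.trn import (
    TRN,
    UndefinedMetricError,
    booleanize,
    filter_de,
    krackhardt_hierarchy,
    prune_pkn,
    signal_dependent_fraction,
)

from conftest import edge_df


def de_row(gene, lfc, p1, p2, padj=0.01):
    return {"gene": gene, "avg_log_fc": lfc, "p_adj": padj,
            "pct_cond1": p1, "pct_cond2": p2}


class TestFilterDe:
    @pytest.mark.parametrize(
        "lfc,p1,p2,kept",
        [
            (0.30, 0.05, 0.05, True),   # passes on fold change alone
            (0.10, 0.15, 0.12, True),   # passes on presence in both conditions
            (0.10, 0.15, 0.05, False),  # neither disjunct holds
            (0.25, 0.05, 0.05, False),  # fold-change threshold is strict
            (-0.30, 0.05, 0.05, True),  # absolute value
            (0.10, 0.10, 0.15, False),  # presence threshold is strict too
        ],
    )
    def test_keep_drop_decisions(self, lfc, p1, p2, kept):
        table = pd.DataFrame([de_row("g", lfc, p1, p2)])
        assert (len(filter_de(table)) == 1) is kept


class TestBooleanize:
    def test_sign_maps_to_state_and_zero_is_excluded(self):
        table = pd.DataFrame(
            [de_row("up", 0.5, 0.2, 0.2), de_row("down", -0.3, 0.2, 0.2),
             de_row("flat", 0.0, 0.2, 0.2)])
        assert booleanize(table) == {"up": 1, "down": 0}


# ---------------------------------------------------------------------------
# pruning


def bf_prune(pkn, profile, tf_universe):
    """Brute-force oracle: lexicographic-best consistent edge subset by
    enumeration over all edge subsets."""
    cand = [
        (s, t, int(w)) for s, t, w in pkn.itertuples(index=False)
        if s in tf_universe and s in profile and t in profile
    ]
    cand = list(dict.fromkeys(cand))
    best, best_key = [], (-1, -1)
    for r in range(len(cand) + 1):
        for subset in itertools.combinations(cand, r):
            ok = True
            by_target = {}
            for s, t, w in subset:
                by_target.setdefault(t, []).append((s, w))
            for t, ins in by_target.items():
                up_act = any(profile[s] == 1 and w == 1 for s, w in ins)
                up_inh = any(profile[s] == 1 and w == -1 for s, w in ins)
                if profile[t] == 1 and (up_inh or not up_act):
                    ok = False
                    break
                if profile[t] == 0 and (up_act and not up_inh):
                    ok = False
                    break
            if ok:
                key = (len(by_target), len(subset))
                if key > best_key:
                    best, best_key = list(subset), key
    return set(best)


class TestPrunePkn:
    def test_textbook_inhibition_kept(self):
        trn = prune_pkn(edge_df([("A", "B", -1)]), {"A": 1, "B": 0}, {"A"})
        assert set(map(tuple, trn.edges.to_numpy())) == {("A", "B", -1)}

    def test_activator_excused_by_dominant_inhibitor(self):
        trn = prune_pkn(
            edge_df([("A", "B", 1), ("C", "B", -1)]),
            {"A": 1, "B": 0, "C": 1}, {"A", "C"})
        assert len(trn.edges) == 2

    def test_lone_up_activator_into_down_gene_removed(self):
        trn = prune_pkn(edge_df([("A", "B", 1)]), {"A": 1, "B": 0}, {"A"})
        assert trn.edges.empty
        assert trn.n == 0

    def test_non_tf_sources_discarded(self):
        trn = prune_pkn(
            edge_df([("A", "B", 1), ("X", "B", 1)]),
            {"A": 1, "B": 1, "X": 1}, {"A"})
        assert set(trn.edges["source"]) == {"A"}

    def test_output_subset_of_input_and_idempotent(self):
        rng = np.random.default_rng(7)
        genes = list("ABCDEF")
        for _ in range(25):
            rows = {
                (genes[rng.integers(3)], genes[rng.integers(6)],
                 int(rng.choice([-1, 1])))
                for _ in range(rng.integers(2, 10))
            }
            pkn = edge_df(sorted(rows))
            profile = {g: int(rng.integers(2)) for g in genes}
            trn = prune_pkn(pkn, profile, set(genes[:3]))
            kept = set(map(tuple, trn.edges.to_numpy()))
            assert kept <= set(map(tuple, pkn.to_numpy()))
            again = prune_pkn(trn.edges, profile, set(genes[:3]))
            assert set(map(tuple, again.edges.to_numpy())) == kept

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        genes = list("ABCDE")
        for _ in range(40):
            n_edges = rng.integers(1, 13)
            rows = {
                (genes[rng.integers(3)], genes[rng.integers(5)],
                 int(rng.choice([-1, 1])))
                for _ in range(n_edges)
            }
            pkn = edge_df(sorted(rows))
            profile = {g: int(rng.integers(2)) for g in genes}
            tfs = set(genes[:3])
            got = set(map(tuple, prune_pkn(pkn, profile, tfs).edges.to_numpy()))
            assert got == bf_prune(pkn, profile, tfs)

    def test_enumeration_and_closed_form_agree(self):
        from rejuvenet.trn import _best_subset_closed_form, _best_subset_enumerate
        rng = np.random.default_rng(3)
        for _ in range(200):
            sources = [f"t{i}" for i in range(rng.integers(1, 7))]
            profile = {s: int(rng.integers(2)) for s in sources}
            profile["g"] = int(rng.integers(2))
            edges = [(s, int(rng.choice([-1, 1]))) for s in sources]
            assert sorted(_best_subset_enumerate(edges, profile["g"], profile)) == \
                sorted(_best_subset_closed_form(edges, profile["g"], profile))

    def test_noiseless_planted_network_survives_intact(self):
        for seed in range(5):
            planted = make_planted_trn(
                SimSpec(n_tfs=4, n_targets=8, inhibitor_fraction=0.4, seed=seed))
            trn = prune_pkn(
                planted.pkn, planted.profile,
                {s for s in planted.pkn["source"]})
            assert len(trn.edges) == len(planted.pkn)

    def test_empty_profile_gives_empty_trn(self, caplog):
        with caplog.at_level("WARNING"):
            trn = prune_pkn(edge_df([("A", "B", 1)]), {}, {"A"})
        assert trn.n == 0

    def test_self_loop_allowed(self):
        trn = prune_pkn(edge_df([("A", "A", 1)]), {"A": 1}, {"A"})
        assert len(trn.edges) == 1


# ---------------------------------------------------------------------------
# Krackhardt hierarchy


def bf_hierarchy(adj):
    """Reachability-matrix oracle on a dense adjacency matrix."""
    n = adj.shape[0]
    reach = adj.astype(bool).copy()
    for k in range(n):
        reach |= reach[:, k][:, None] & reach[k, :][None, :]
    sym = reachable = 0
    for i in range(n):
        for j in range(i + 1, n):
            if reach[i, j] or reach[j, i]:
                reachable += 1
                if reach[i, j] and reach[j, i]:
                    sym += 1
    if reachable == 0:
        return None
    return 1 - sym / reachable


def graph_from_adj(adj):
    g = nx.DiGraph()
    n = adj.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                g.add_edge(i, j)
    return g


class TestKrackhardtHierarchy:
    def test_out_tree_is_pure_hierarchy(self):
        g = nx.balanced_tree(2, 3, create_using=nx.DiGraph)
        assert krackhardt_hierarchy(g) == 1.0

    def test_two_cycle_is_zero(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        assert krackhardt_hierarchy(g) == 0.0

    def test_three_node_partial_cycle(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "B")])
        assert krackhardt_hierarchy(g) == pytest.approx(2 / 3)

    def test_no_reachable_pair_is_undefined(self):
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B"])
        with pytest.raises(UndefinedMetricError):
            krackhardt_hierarchy(g)

    def test_exhaustive_three_node_digraphs_match_oracle(self):
        for bits in range(1, 2 ** 6):
            adj = np.zeros((3, 3), dtype=bool)
            for b, (i, j) in enumerate(
                    (i, j) for i in range(3) for j in range(3) if i != j):
                adj[i, j] = bool(bits >> b & 1)
            expected = bf_hierarchy(adj)
            g = graph_from_adj(adj)
            if expected is None:
                with pytest.raises(UndefinedMetricError):
                    krackhardt_hierarchy(g)
            else:
                assert krackhardt_hierarchy(g) == pytest.approx(expected)

    def test_random_five_node_digraphs_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            adj = rng.random((5, 5)) < 0.35
            np.fill_diagonal(adj, False)
            expected = bf_hierarchy(adj)
            if expected is None:
                continue
            assert krackhardt_hierarchy(graph_from_adj(adj)) == pytest.approx(expected)


class TestSignalDependentFraction:
    def setup_method(self):
        self.trn = TRN(edge_df([("T1", "g1", 1)]))
        # unexplained DE genes g2..g5, each with a PKN regulator
        self.pkn = edge_df(
            [("T1", "g1", 1), ("S1", "g2", 1), ("S2", "g3", -1),
             ("S1", "g4", 1), ("T9", "g5", 1)])
        self.de = ["g1", "g2", "g3", "g4", "g5"]

    def test_three_of_four_unexplained_covered(self):
        assert signal_dependent_fraction(
            self.de, self.trn, self.pkn, {"S1", "S2"}) == pytest.approx(0.75)

    def test_all_and_none(self):
        assert signal_dependent_fraction(
            self.de, self.trn, self.pkn, {"S1", "S2", "T9"}) == 1.0
        assert signal_dependent_fraction(self.de, self.trn, self.pkn, set()) == 0.0

    def test_empty_denominator_signalled(self):
        with pytest.raises(UndefinedMetricError):
            signal_dependent_fraction(["g1"], self.trn, self.pkn, {"S1"})
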