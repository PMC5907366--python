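import itertools

import numpy as np
import pytest

import mitodiag as md
from mitodiag import AlignmentError
from mitodiag.parsimony import FilterConfig, fitch_steps_matrix, _state_bitmasks

from conftest import random_alignment


# -- independent oracles ------------------------------------------------

def sankoff_steps(tree, leaf_states, n_states):
    """Unit-cost Sankoff DP: exact minimum over all internal labelings.

    ``leaf_states`` maps leaf label -> set of allowed state indices.
    """
    INF = 10 ** 9

    def cost(node):
        if node.is_leaf():
            allowed = leaf_states[node.taxon.label]
            return [0 if s in allowed else INF for s in range(n_states)]
        child_costs = [cost(c) for c in node.child_nodes()]
        out = []
        for s in range(n_states):
            tot = 0
            for cc in child_costs:
                tot += min(cc[t] + (0 if t == s else 1)
                           for t in range(n_states))
            out.append(tot)
        return out

    return min(cost(tree.seed_node))


def enumeration_steps(tree, leaf_states, n_states):
    """Literal exhaustive enumeration over all internal-node labelings."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = None
    for labels in itertools.product(range(n_states), repeat=len(internals)):
        assign = dict(zip(map(id, internals), labels))
        total = 0
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            ps = assign[id(node.parent_node)]
            if node.is_leaf():
                # an ambiguous leaf picks its cheapest allowed state
                total += 0 if ps in leaf_states[node.taxon.label] else 1
            else:
                total += 0 if assign[id(node)] == ps else 1
        if best is None or total < best:
            best = total
    return best


def random_instance(rng, max_leaves=8, max_states=6, allow_polytomy=True):
    n_leaves = int(rng.integers(4, max_leaves + 1))
    n_states = int(rng.integers(2, max_states + 1))
    t = md.random_tree(n_leaves, rng)
    if allow_polytomy and rng.random() < 0.4:
        # collapse a random internal edge to make a multifurcation
        internals = [n for n in t.preorder_node_iter()
                     if not n.is_leaf() and n.parent_node is not None]
        if internals:
            victim = internals[int(rng.integers(len(internals)))]
            parent = victim.parent_node
            for c in list(victim.child_nodes()):
                parent.add_child(c)
            parent.remove_child(victim)
    states = {}
    for lf in t.leaf_node_iter():
        r = rng.random()
        if r < 0.1:
            states[lf.taxon.label] = set(range(n_states))  # missing
        elif r < 0.2:
            k = int(rng.integers(2, n_states + 1))
            states[lf.taxon.label] = set(
                rng.choice(n_states, size=k, replace=False).tolist())
        else:
            states[lf.taxon.label] = {int(rng.integers(n_states))}
    return t, states, n_states


def run_fitch(tree, leaf_states, n_states):
    alphabet = [chr(ord("A") + i) for i in range(n_states)]
    mapped = {leaf: {alphabet[s] for s in ss}
              for leaf, ss in leaf_states.items()}
    return md.fitch_steps(mapped, tree, state_space=alphabet)


class TestFitchSteps:
    def test_constant_site_zero_steps(self, quartet_tree):
        assert md.fitch_steps({t: "A" for t in "t1 t2 t3 t4".split()},
                              quartet_tree) == 0

    def test_grouped_states_one_step(self, quartet_tree):
        st = {"t1": "A", "t2": "A", "t3": "G", "t4": "G"}
        assert md.fitch_steps(st, quartet_tree) == 1

    def test_alternating_states_two_steps(self, quartet_tree):
        st = {"t1": "A", "t2": "G", "t3": "A", "t4": "G"}
        assert md.fitch_steps(st, quartet_tree) == 2

    def test_missing_never_forces_a_step(self, quartet_tree):
        st = {"t1": "A", "t2": "-", "t3": "?", "t4": "A"}
        assert md.fitch_steps(st, quartet_tree) == 0

    def test_leaf_absent_errors(self, quartet_tree):
        with pytest.raises(AlignmentError, match="absent"):
            md.fitch_steps({"t1": "A"}, quartet_tree)

    def test_matches_sankoff_oracle_200_random_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            t, states, k = random_instance(rng)
            assert run_fitch(t, states, k) == sankoff_steps(t, states, k)

    def test_sankoff_oracle_matches_full_enumeration_small(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            t, states, k = random_instance(rng, max_leaves=5, max_states=3,
                                           allow_polytomy=True)
            assert sankoff_steps(t, states, k) == enumeration_steps(t, states, k)

    def test_rooting_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            t, states, k = random_instance(rng, allow_polytomy=False)
            base = run_fitch(t, states, k)
            t2 = t.clone(depth=1)
            edges = [e for e in t2.preorder_edge_iter()
                     if e.head_node.parent_node is not None]
            e = edges[int(rng.integers(len(edges)))]
            t2.reroot_at_edge(e, update_bipartitions=False)
            assert run_fitch(t2, states, k) == base

    def test_leaf_order_invariance(self, quartet_tree):
        st = {"t1": "A", "t2": "C", "t3": "G", "t4": "G"}
        a = md.fitch_steps(st, quartet_tree)
        b = md.fitch_steps(dict(reversed(list(st.items()))), quartet_tree)
        assert a == b


class TestSiteSignals:
    def test_invariant_singleton_homoplastic(self):
        t = md.read_tree("(((t1,t2),(t3,t4)),((t5,t6),(t7,t8)));")
        m = np.array([list("AAA"), list("AGA"), list("AAG"),
                      list("AAA"), list("AAG"), list("AAA"),
                      list("AAG"), list("AAA")])
        a = md.Alignment([f"t{i + 1}" for i in range(8)], m)
        sig = md.site_signals(a, FilterConfig(tree=t, ci_threshold=0.3))
        inv = sig.iloc[0]
        assert (inv.m, inv.s, inv.CI, inv.retained) == (0, 0, 1.0, True)
        single = sig.iloc[1]
        assert (single.m, single.s, single.CI) == (1, 1, 1.0)
        homop = sig.iloc[2]  # G scattered over the tree: m=1, s=3
        assert homop.m == 1 and homop.s == 3
        assert homop.CI == pytest.approx(1 / 3)

    def test_too_few_shared_taxa(self):
        t = md.read_tree("((t1,t2),t3);")
        a = md.Alignment(["t1", "t2", "t3"], np.array([list("A")] * 3))
        with pytest.raises(AlignmentError, match="4"):
            md.site_signals(a, FilterConfig(tree=t))

    def test_alignment_taxon_missing_from_tree(self, quartet_tree):
        a = md.Alignment(["t1", "t2", "t3", "zz"],
                         np.array([list("A")] * 4))
        with pytest.raises(AlignmentError, match="zz"):
            md.site_signals(a, FilterConfig(tree=quartet_tree))

    def test_ci_invariants_on_10000_random_sites(self):
        rng = np.random.default_rng(7)
        a = random_alignment(rng, 12, 10_000, missing_frac=0.1)
        t = md.random_tree(12, rng)
        sig = md.site_signals(a, FilterConfig(tree=t, ci_threshold=0.3))
        m, s, ci = sig.m.to_numpy(), sig.s.to_numpy(), sig.CI.to_numpy()
        assert (m <= s).all()
        nonmissing = (~a.is_missing()).sum(axis=0)
        assert (s <= np.maximum(nonmissing - 1, 0)).all()
        pos = s > 0
        assert np.allclose(ci[pos], m[pos] / s[pos])
        assert (ci[~pos] == 1.0).all()
        assert sig.retained[~pos].all()
        assert ((ci > 0) & (ci <= 1)).all()

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        a = random_alignment(rng, 10, 2000)
        t = md.random_tree(10, rng)
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.8, 1.0):
            sig = md.site_signals(a, FilterConfig(tree=t, ci_threshold=thr))
            removed = set(sig.site[~sig.retained])
            if prev is not None:
                assert prev <= removed
            prev = removed

    def test_threshold_validation(self, quartet_tree):
        with pytest.raises(AlignmentError):
            FilterConfig(tree=quartet_tree, ci_threshold=1.01)


class TestApplyFilter:
    def test_threshold_zero_is_identity(self, quartet_tree):
        rng = np.random.default_rng(5)
        a = random_alignment(rng, 4, 300)
        a = md.Alignment(["t1", "t2", "t3", "t4"], a.matrix)
        sig = md.site_signals(a, FilterConfig(tree=quartet_tree,
                                              ci_threshold=0.0))
        filt, removed = md.apply_filter(a, sig)
        assert filt.n_sites == a.n_sites and not removed.any()

    def test_all_invariant_identity(self, quartet_tree):
        a = md.Alignment(["t1", "t2", "t3", "t4"],
                         np.array([list("AAAA")] * 4))
        sig = md.site_signals(a, FilterConfig(tree=quartet_tree))
        filt, removed = md.apply_filter(a, sig)
        assert filt.n_sites == 4 and not removed.any()

    def test_everything_removed_errors(self, quartet_tree):
        # both columns alternate states across the split: CI = 0.5 < 0.6
        m = np.array([list("AA"), list("GG"), list("AG"), list("GA")])
        a = md.Alignment(["t1", "t2", "t3", "t4"], m)
        sig = md.site_signals(a, FilterConfig(tree=quartet_tree,
                                              ci_threshold=0.6))
        with pytest.raises(AlignmentError, match="threshold"):
            md.apply_filter(a, sig)

    def test_idempotent_at_same_threshold(self, quartet_tree):
        rng = np.random.default_rng(6)
        a = random_alignment(rng, 4, 500)
        a = md.Alignment(["t1", "t2", "t3", "t4"], a.matrix)
        cfg = FilterConfig(tree=quartet_tree, ci_threshold=0.3)
        filt, _ = md.apply_filter(a, md.site_signals(a, cfg))
        filt2, removed2 = md.apply_filter(filt, md.site_signals(filt, cfg))
        assert not removed2.any()


class TestRemovalSummary:
    def _gene_aln(self, n_codons=10):
        n = n_codons * 3
        gene = np.array(["g1"] * n, dtype=object)
        cpos = np.tile([1, 2, 3], n_codons)
        m = np.array([list("A" * n)] * 4)
        return md.Alignment(["t1", "t2", "t3", "t4"], m, "DNA", gene, cpos)

    def test_one_full_codon_removed(self):
        a = self._gene_aln(10)
        removed = np.zeros(30, bool)
        removed[3:6] = True
        df = md.removal_summary(removed, a)
        row = df[df.gene == "g1"].iloc[0]
        assert row.aa_removal_ratio_full == pytest.approx(0.1)
        assert row.aa_removal_ratio_any == pytest.approx(0.1)

    def test_partial_codons(self):
        a = self._gene_aln(10)
        removed = np.zeros(30, bool)
        removed[[0, 4, 8]] = True  # one position in each of 3 codons
        df = md.removal_summary(removed, a)
        row = df[df.gene == "g1"].iloc[0]
        assert row.aa_removal_ratio_full == 0
        assert row.aa_removal_ratio_any == pytest.approx(0.3)

    def test_totals_consistent(self):
        rng = np.random.default_rng(4)
        from mitodiag.simulate import make_benchmark_scenario
        ds = make_benchmark_scenario("two_gene_rates", 2)
        removed = rng.random(ds.alignment.n_sites) < 0.2
        df = md.removal_summary(removed, ds.alignment)
        per_gene = df[df.gene != "ALL"]
        assert per_gene.sites_removed.sum() == removed.sum()
        assert (df[df.gene == "ALL"].sites_removed.iloc[0]
                == removed.sum())


class TestMonophyly:
    def test_whole_ingroup_true(self):
        t = md.read_tree("((a,b),(c,d));")
        assert md.is_monophyletic(t, {"a", "b", "c"}, "d")

    def test_single_leaf_true(self):
        t = md.read_tree("((a,b),(c,d));")
        assert md.is_monophyletic(t, {"a"}, "d")

    def test_split_pair_false(self):
        t = md.read_tree("((a,b),(c,d));")
        assert not md.is_monophyletic(t, {"a", "c"}, "d")

    def test_outgroup_not_in_tree(self):
        t = md.read_tree("((a,b),(c,d));")
        with pytest.raises(AlignmentError):
            md.is_monophyletic(t, {"a", "b"}, "zz")

    def test_overlap_rejected(self):
        t = md.read_tree("((a,b),(c,d));")
        with pytest.raises(AlignmentError):
            md.is_monophyletic(t, {"a", "d"}, "d")
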