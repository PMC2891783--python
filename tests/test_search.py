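import itertools

import numpy as np
import pytest

from treecarto.tree_core import (TaxonMap, read_newick, enumerate_trees,
                                 random_tree)
from treecarto.search import (Alignment, fitch_score, tbr_neighborhood,
                              nni_neighborhood, score_spectrum, hill_climb)
from treecarto.cli_fixtures import simulate_alignment


def brute_force_parsimony(t, a):
    """Independent oracle: minimize changes over all internal state
    assignments, per site."""
    n = t.n
    internals = [v for v in t.adj if v >= n]
    edges = t.edges()
    total = 0
    for site in range(a.n_sites):
        leaf_states = {v: a.sites[v, site] for v in range(n)}
        best = None
        for combo in itertools.product((1, 2, 4, 8), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            assign.update(leaf_states)
            changes = 0
            # a change on an edge is avoided iff the state sets intersect
            # (internal states are single bits; leaves may be ambiguous)
            for u, v in edges:
                if not (assign[u] & assign[v]):
                    changes += 1
            best = changes if best is None else min(best, changes)
        total += best
    return total


def tbr_adjacent_oracle(t1, t2):
    """Independent TBR adjacency check via restrictions: t2 is one move
    from t1 iff some bipartition induced by an edge of t1 is also induced
    by an edge of t2 and the two restricted subtrees agree."""
    if t1 == t2:
        return False
    n = t1.n

    def edge_leafsets(t):
        out = []
        for u, v in t.edges():
            side = _leaves_beyond(t, u, v)
            out.append(frozenset(side))
        return out

    def restrict(t, leaves):
        # split set of the induced subtree on `leaves`, re-labeled
        sub = sorted(leaves)
        relabel = {x: i for i, x in enumerate(sub)}
        masks = set()
        for s in t.splits():
            inner = set(s.indices) & leaves
            comp = leaves - set(s.indices)
            for grp in (inner, comp):
                if 2 <= len(grp) <= len(leaves) - 2:
                    bits = 0
                    for x in grp:
                        bits |= 1 << relabel[x]
                    low = bits if not bits & 1 else \
                        ((1 << len(sub)) - 1) & ~bits
                    masks.add(low)
        return frozenset(masks)

    sets1 = {fs for fs in edge_leafsets(t1)}
    sets2 = {fs for fs in edge_leafsets(t2)}
    for L in sets1 & sets2:
        Lc = frozenset(range(n)) - L
        if restrict(t1, set(L)) == restrict(t2, set(L)) and \
                restrict(t1, set(Lc)) == restrict(t2, set(Lc)):
            return True
    return False


def _leaves_beyond(t, u, v):
    """Leaves on v's side of edge (u, v)."""
    seen = {v}
    stack = [v]
    out = []
    while stack:
        x = stack.pop()
        if x < t.n:
            out.append(x)
        for y in t.adj[x]:
            if y not in seen and not (x == v and y == u):
                seen.add(y)
                stack.append(y)
    return out


# ---------------------------------------------------------------------------
# alignment container


def test_alignment_from_sequences():
    a = Alignment.from_sequences({"1": "ACGT", "2": "ACGA", "3": "AC-T"})
    assert a.n_sites == 4
    assert a.sites[2, 2] == 15  # gap = any state


def test_alignment_rejects_ragged():
    with pytest.raises(ValueError):
        Alignment.from_sequences({"1": "AC", "2": "A", "3": "AC"})


def test_alignment_fasta_round_trip(tmp_path):
    a = Alignment.from_sequences({"x": "ACGT", "y": "TTGA", "z": "CCCC"})
    p = tmp_path / "a.fasta"
    a.to_fasta(p)
    b = Alignment.from_fasta(p)
    assert np.array_equal(a.sites, b.sites)
    assert a.taxa == b.taxa


# ---------------------------------------------------------------------------
# Fitch


def test_fitch_single_change():
    a = Alignment.from_sequences({"1": "A", "2": "A", "3": "C", "4": "C"})
    assert fitch_score(read_newick("((1,2),(3,4));", a.taxa), a) == 1


def test_fitch_two_changes_matches_brute_force():
    a = Alignment.from_sequences({"1": "A", "2": "A", "3": "C", "4": "C"})
    t = read_newick("((1,3),(2,4));", a.taxa)
    assert fitch_score(t, a) == 2 == brute_force_parsimony(t, a)


def test_fitch_invariant_column_zero():
    a = Alignment.from_sequences({s: "G" for s in "12345"})
    for t in enumerate_trees(5, a.taxa):
        assert fitch_score(t, a) == 0


def test_fitch_matches_brute_force_random_n5(rng):
    taxa = TaxonMap([str(i) for i in range(1, 6)])
    for _ in range(5):
        seqs = {lab: "".join(rng.choice(list("ACGT"), size=4))
                for lab in taxa.labels}
        a = Alignment.from_sequences(seqs, taxa)
        for t in list(enumerate_trees(5, taxa))[::4]:
            assert fitch_score(t, a) == brute_force_parsimony(t, a)


def test_fitch_rooting_invariance_n6(rng):
    # score must not depend on the internal traversal root; compare
    # against re-parsed rotations of the same topology
    taxa = TaxonMap([str(i) for i in range(1, 7)])
    seqs = {lab: "".join(rng.choice(list("ACGT"), size=30))
            for lab in taxa.labels}
    a = Alignment.from_sequences(seqs, taxa)
    forms = ["((1,2),(3,4),(5,6));", "((3,4),(1,2),(5,6));",
             "(((3,4),(5,6)),1,2);"]
    scores = {fitch_score(read_newick(f, taxa), a) for f in forms}
    assert len(scores) == 1


def test_fitch_taxa_mismatch():
    a = Alignment.from_sequences({"1": "A", "2": "C", "3": "G", "4": "T"})
    t = read_newick("((a,b),(c,d));")
    with pytest.raises(ValueError):
        fitch_score(t, a)


# ---------------------------------------------------------------------------
# TBR / NNI neighbourhoods


def test_tbr_n4_reaches_both_other_topologies():
    t = read_newick("((1,2),(3,4));")
    nb = tbr_neighborhood(t)
    assert len(nb) == 2
    assert nb == set(x for x in enumerate_trees(4, t.taxa) if x != t)


def test_tbr_matches_restriction_oracle_exhaustive_n5(all_trees5):
    for t in all_trees5[:6]:
        nb = tbr_neighborhood(t)
        oracle = {x for x in all_trees5 if tbr_adjacent_oracle(t, x)}
        assert nb == oracle


def test_tbr_neighborhood_size_n5(tree5, all_trees5):
    # 2(n-3)(2n-7) = 12 distinct neighbours at n=5; the remaining two
    # topologies are two moves away
    nb = tbr_neighborhood(tree5)
    assert len(nb) == 12
    assert tree5 not in nb


def test_tbr_symmetric_exhaustive_n5(all_trees5):
    nbs = {t: tbr_neighborhood(t) for t in all_trees5}
    for a in all_trees5:
        for b in all_trees5:
            if a != b:
                assert (b in nbs[a]) == (a in nbs[b])


def test_tbr_symmetric_spot_check_n6(rng):
    a = random_tree(6, rng)
    for b in tbr_neighborhood(a):
        assert a in tbr_neighborhood(b)


def test_nni_subset_of_tbr():
    for nwk in ("((1,2),3,(4,5));", "((1,2),(3,4),(5,6));"):
        t = read_newick(nwk)
        assert nni_neighborhood(t) <= tbr_neighborhood(t)


def test_nni_count():
    t = read_newick("((1,2),(3,4),(5,6));")
    assert len(nni_neighborhood(t)) == 2 * (6 - 3)


# ---------------------------------------------------------------------------
# spectra and hill climbing


def test_spectrum_invariant_alignment_all_zero(tree5):
    a = Alignment.from_sequences({s: "AAAA" for s in "12345"}, tree5.taxa)
    hist = score_spectrum(tree5, a)
    assert set(hist) == {0}


def test_spectrum_conservation_and_brute_recount(rng):
    t = random_tree(6, rng)
    a = simulate_alignment(t, sites=40, p_change=0.2, seed=1)
    hist = score_spectrum(t, a)
    nb = tbr_neighborhood(t)
    assert sum(hist.values()) == len(nb)
    recount = {}
    for x in nb:
        s = fitch_score(x, a)
        recount[s] = recount.get(s, 0) + 1
    assert dict(hist) == recount


def test_hill_climb_from_global_optimum_single_entry():
    a = Alignment.from_sequences({"1": "AA", "2": "AA", "3": "CC",
                                  "4": "CC", "5": "CT"})
    trees = list(enumerate_trees(5, a.taxa))
    best = min(trees, key=lambda t: fitch_score(t, a))
    trace = hill_climb(a, best, sampling_period=10)
    assert len(trace.accepted) == 1


def test_hill_climb_monotone_strictly_decreasing(rng):
    t = random_tree(7, rng)
    a = simulate_alignment(t, sites=60, p_change=0.15, seed=9)
    start = random_tree(7, rng, taxa=t.taxa)
    trace = hill_climb(a, start, sampling_period=50)
    scores = [s for _, s in trace.accepted]
    assert all(x > y for x, y in zip(scores, scores[1:]))
    assert scores[-1] <= scores[0]


def test_hill_climb_restarts_find_exhaustive_optimum():
    gen = np.random.default_rng(123)
    true = random_tree(6, gen)
    a = simulate_alignment(true, sites=80, p_change=0.1, seed=4)
    exhaustive_best = min(fitch_score(t, a)
                          for t in enumerate_trees(6, true.taxa))
    found = min(hill_climb(a, random_tree(6, gen, taxa=true.taxa),
                           sampling_period=100).best[1]
                for _ in range(8))
    assert found == exhaustive_best


def test_hill_climb_sampling_period():
    a = Alignment.from_sequences({"1": "AC", "2": "AG", "3": "CT",
                                  "4": "GA", "5": "TT"})
    start = read_newick("((1,2),3,(4,5));", a.taxa)
    trace = hill_climb(a, start, sampling_period=3)
    assert trace.sampling_period == 3
    assert all(isinstance(s, int) for _, s in trace.sampled_rejected)
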