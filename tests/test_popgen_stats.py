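from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invclines.popgen_stats import (count_differences, hudson_fst_site,
                                    minimum_spanning_network,
                                    pairwise_divergence, windowed_fst)

# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------


def test_fixed_difference_gives_fst_one():
    num, den = hudson_fst_site(1.0, 0.0, 1000, 1000)
    assert num / den == pytest.approx(1.0)


def test_identical_frequencies_give_fst_near_zero():
    num, den = hudson_fst_site(0.5, 0.5, 10**7, 10**7)
    assert abs(num / den) < 1e-5


def test_hand_evaluated_site():
    num, den = hudson_fst_site(0.9, 0.1, 50, 50)
    assert num == pytest.approx(0.64 - 2 * 0.09 / 49)
    assert den == pytest.approx(0.82)
    assert num / den == pytest.approx(0.7760, abs=5e-5)


@given(p1=st.floats(0, 1), p2=st.floats(0, 1),
       n1=st.integers(2, 500), n2=st.integers(2, 500))
def test_components_match_hand_formula(p1, p2, n1, n2):
    num, den = hudson_fst_site(p1, p2, n1, n2)
    by_hand_num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
        - p2 * (1 - p2) / (n2 - 1)
    by_hand_den = p1 * (1 - p2) + p2 * (1 - p1)
    if by_hand_den == 0 and p1 == p2:
        assert (num, den) == (0.0, 0.0)
    else:
        assert abs(num - by_hand_num) < 1e-12
        assert abs(den - by_hand_den) < 1e-12


def test_hudson_input_validation():
    with pytest.raises(ValueError):
        hudson_fst_site(0.5, 0.5, 1, 10)
    with pytest.raises(ValueError):
        hudson_fst_site(1.5, 0.5, 10, 10)


def test_windowed_fst_group_swap_and_self_comparison(default_sim):
    _, g, truth = default_sim
    ss = [s for s in g.samples if truth.karyotypes[s] == "SS"]
    nn = [s for s in g.samples if truth.karyotypes[s] == "NN"]
    a = windowed_fst(g, ss, nn, interval=truth.inversion)
    b = windowed_fst(g, nn, ss, interval=truth.inversion)
    assert a.fst == pytest.approx(b.fst)
    self_cmp = windowed_fst(g, ss, ss, interval=truth.inversion)
    assert abs(self_cmp.fst) < 0.02
    w = self_cmp.windows["fst"].dropna()
    assert (w.abs() < 0.1).all()


def test_single_polymorphic_site_ratio_equals_site_value(default_sim):
    _, g, truth = default_sim
    ss = [s for s in g.samples if truth.karyotypes[s] == "SS"][:5]
    nn = [s for s in g.samples if truth.karyotypes[s] == "NN"][:5]
    res = windowed_fst(g, ss, nn)
    one = res.sites.iloc[0]
    assert one["num"] / one["den"] == pytest.approx(
        windowed_fst(g, ss, nn,
                     interval=(int(one["pos"]), int(one["pos"]) + 1)).fst)


def test_inside_inversion_fst_hits_calibrated_target(default_sim):
    from invclines.synthetic_data import expected_inversion_fst
    cfg, g, truth = default_sim
    ss = [s for s in g.samples if truth.karyotypes[s] == "SS"]
    nn = [s for s in g.samples if truth.karyotypes[s] == "NN"]
    inside = windowed_fst(g, ss, nn, interval=truth.inversion).fst
    outside = windowed_fst(g, ss, nn,
                           interval=(truth.inversion[1],
                                     cfg.chrom_length)).fst
    assert inside == pytest.approx(expected_inversion_fst(cfg), abs=0.05)
    assert inside > outside + 0.3


# ---------------------------------------------------------------------------
# pairwise divergence
# ---------------------------------------------------------------------------

def test_divergence_paper_scale_example():
    a = "A" * 472 + "C" * 16
    b = "A" * 488
    dm = pairwise_divergence({"n": a, "s": b})
    assert dm.counts.loc["n", "s"] == 16
    assert dm.percent.loc["n", "s"] == 3.3


def test_identical_sequences_diverge_zero():
    dm = pairwise_divergence({"a": "ACGT", "b": "ACGT"})
    assert dm.counts.loc["a", "b"] == 0
    assert dm.percent.loc["a", "b"] == 0.0


def test_iupac_and_n_handling():
    # R is compatible with A; N drops the position from the alignment
    d, eff = count_differences("ARCN", "AACC")
    assert (d, eff) == (0, 3)
    d, eff = count_differences("ARC", "ACC")  # R vs C incompatible
    assert (d, eff) == (1, 3)
    with pytest.raises(ValueError):
        count_differences("AC", "A")


def test_divergence_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(42)
    seqs = {f"h{i}": "".join(rng.choice(list("ACGT"), 100)) for i in range(6)}
    dm = pairwise_divergence(seqs)
    names = list(seqs)
    for a, b in combinations(names, 2):
        naive = sum(x != y for x, y in zip(seqs[a], seqs[b]))
        assert dm.counts.loc[a, b] == naive
    # Hamming triangle inequality
    for a, b, c in combinations(names, 3):
        assert dm.counts.loc[a, c] <= dm.counts.loc[a, b] + dm.counts.loc[b, c]


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

def _brute_force_msn(haps: dict[str, str]) -> set[frozenset]:
    """Union of all minimum spanning trees by exhaustive enumeration."""
    names = list(haps)
    k = len(names)
    edges = {}
    for i, j in combinations(range(k), 2):
        edges[(i, j)] = sum(x != y for x, y in zip(haps[names[i]],
                                                   haps[names[j]]))
    best_w = None
    union: set[frozenset] = set()
    for tree in combinations(edges, k - 1):
        g = nx.Graph(tree)
        if g.number_of_nodes() != k or not nx.is_connected(g):
            continue
        w = sum(edges[e] for e in tree)
        if best_w is None or w < best_w:
            best_w = w
            union = set(frozenset(e) for e in tree)
        elif w == best_w:
            union |= set(frozenset(e) for e in tree)
    return union


def test_identical_haplotypes_collapse():
    net = minimum_spanning_network({"x": "A", "y": "A", "z": "C"})
    assert net.number_of_nodes() == 2
    mult = {d["sequence"]: d["multiplicity"] for _, d in net.nodes(data=True)}
    assert mult == {"A": 2, "C": 1}
    (u, v, w), = net.edges(data="weight")
    assert w == 1


def test_star_topology_excludes_the_long_edge():
    # AA is one step from both; CA-AC is two steps and in no MST
    net = minimum_spanning_network({"a": "AA", "b": "CA", "c": "AC"})
    seq_of = {n: d["sequence"] for n, d in net.nodes(data=True)}
    edge_seqs = {frozenset((seq_of[u], seq_of[v])) for u, v in net.edges}
    assert edge_seqs == {frozenset(("AA", "CA")), frozenset(("AA", "AC"))}


def test_equidistant_triangle_keeps_all_edges():
    net = minimum_spanning_network({"a": "AA", "b": "AC", "c": "AG"})
    assert net.number_of_edges() == 3


@pytest.mark.parametrize("seed", range(8))
def test_msn_equals_brute_force_union_of_msts(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 8))
    seqs: list[str] = []
    while len(seqs) < k:  # distinct haplotypes over a 2-letter alphabet
        s = "".join(rng.choice(list("AC"), 10))
        if s not in seqs:
            seqs.append(s)
    haps = {f"h{i}": s for i, s in enumerate(seqs)}
    net = minimum_spanning_network(haps)
    seq_of = {n: d["sequence"] for n, d in net.nodes(data=True)}
    got = {frozenset((seq_of[u], seq_of[v])) for u, v in net.edges}
    names = list(haps)
    expected_idx = _brute_force_msn(haps)
    expected = {frozenset((haps[names[i]], haps[names[j]]))
                for e in expected_idx for i, j in [tuple(sorted(e))]}
    assert got == expected


def test_msn_contains_a_standard_mst():
    rng = np.random.default_rng(1)
    haps = {f"h{i}": "".join(rng.choice(list("ACGT"), 20)) for i in range(6)}
    net = minimum_spanning_network(haps)
    # build the complete distance graph and one MST with networkx
    names = {d["sequence"]: n for n, d in net.nodes(data=True)}
    cg = nx.Graph()
    seqs = list(names)
    for a, b in combinations(seqs, 2):
        cg.add_edge(names[a], names[b],
                    weight=sum(x != y for x, y in zip(a, b)))
    mst = nx.minimum_spanning_tree(cg)
    assert set(map(frozenset, mst.edges)) <= set(map(frozenset, net.edges))


def test_msn_single_haplotype_and_empty():
    net = minimum_spanning_network({"only": "ACGT"})
    assert net.number_of_nodes() == 1 and net.number_of_edges() == 0
    with pytest.raises(ValueError):
        minimum_spanning_network({})
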