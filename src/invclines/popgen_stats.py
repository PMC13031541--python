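"""Differentiation and haplotype-divergence statistics.

Hudson's FST in the Bhatia et al. (2013) form, aggregated as a ratio of
averages; IUPAC-aware pairwise divergence of aligned haplotypes; and the
epsilon = 0 minimum spanning network (the union of all minimum spanning
trees of the haplotype distance graph, with identical sequences collapsed
into weighted nodes).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import IUPAC_CODES, GenotypeMatrix


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_fst_site(p1, p2, n1, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson FST components (numerator, denominator).

    ``p1``/``p2`` are sample allele frequencies, ``n1``/``n2`` the numbers
    of sampled alleles. N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1). Sites monomorphic in both groups get (0, 0)
    and are excluded from ratio-of-averages aggregation.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((n1 < 2) | (n2 < 2)):
        raise ValueError("need >= 2 sampled alleles per group")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    mono = (den == 0) & (p1 == p2)
    num = np.where(mono, 0.0, num)
    return num, den


@dataclass
class FstResult:
    """Windowed and global ratio-of-averages Hudson FST for one contrast."""

    sites: pd.DataFrame             # pos, num, den (usable sites only)
    windows: pd.DataFrame           # start, end, n_sites, fst (NaN if empty)
    fst: float                      # global ratio of averages
    groups: tuple[str, str]
    window_size: int


def windowed_fst(g: GenotypeMatrix, group_a: Sequence[str],
                 group_b: Sequence[str],
                 interval: tuple[int, int] | None = None,
                 window: int = 25_000,
                 labels: tuple[str, str] = ("A", "B")) -> FstResult:
    """Hudson FST between two sample groups, windowed over ``interval``.

    Per window FST = sum(numerators) / sum(denominators) over usable sites
    (ratio of averages); the global value is the same ratio over the whole
    interval. Sites with fewer than 4 non-missing alleles in either group
    are excluded; windows without usable sites report NaN, not zero.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 diploids per group")
    pos_all = g.sites["pos"].to_numpy()
    if interval is None:
        interval = (int(pos_all.min()), int(pos_all.max()) + 1)
    mask = g.site_mask(start=interval[0], end=interval[1])
    p1, n1 = g.allele_frequencies(g.sample_index(group_a), mask)
    p2, n2 = g.allele_frequencies(g.sample_index(group_b), mask)
    usable = (n1 >= 4) & (n2 >= 4)
    pos = pos_all[mask][usable]
    num, den = hudson_fst_site(p1[usable], p2[usable],
                               np.maximum(n1[usable], 2), np.maximum(n2[usable], 2))
    informative = den > 0
    pos, num, den = pos[informative], num[informative], den[informative]
    sites = pd.DataFrame({"pos": pos, "num": num, "den": den})

    rows = []
    for start in range(interval[0], interval[1], window):
        end = min(start + window, interval[1])
        w = (pos >= start) & (pos < end)
        d = den[w].sum()
        rows.append({"start": start, "end": end, "n_sites": int(w.sum()),
                     "fst": num[w].sum() / d if d > 0 else np.nan})
    total_den = den.sum()
    global_fst = float(num.sum() / total_den) if total_den > 0 else np.nan
    return FstResult(sites, pd.DataFrame(rows), global_fst, labels, window)


# ---------------------------------------------------------------------------
# pairwise divergence of aligned haplotypes
# ---------------------------------------------------------------------------

def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC_CODES[a] & IUPAC_CODES[b])


def count_differences(a: str, b: str) -> tuple[int, int]:
    """(substitutions, effective length) between two aligned sequences.

    Positions involving N or a gap are excluded from the effective length;
    ambiguity codes compatible with the other base count as a match.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    diff = eff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ("N", "-") or y in ("N", "-"):
            continue
        eff += 1
        if not _compatible(x, y):
            diff += 1
    return diff, eff


@dataclass
class DivergenceMatrix:
    counts: pd.DataFrame            # integer substitution counts
    percent: pd.DataFrame           # 100 * count / effective length, 1 dp


def pairwise_divergence(seqs: Mapping[str, str]) -> DivergenceMatrix:
    """Symmetric substitution-count and percent-divergence matrices."""
    names = list(seqs)
    k = len(names)
    counts = np.zeros((k, k), dtype=int)
    pct = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            d, eff = count_differences(seqs[names[i]], seqs[names[j]])
            counts[i, j] = counts[j, i] = d
            pct[i, j] = pct[j, i] = round(100 * d / eff, 1) if eff else np.nan
    return DivergenceMatrix(pd.DataFrame(counts, index=names, columns=names),
                            pd.DataFrame(pct, index=names, columns=names))


# ---------------------------------------------------------------------------
# epsilon = 0 minimum spanning network
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def minimum_spanning_network(seqs: Mapping[str, str]) -> nx.Graph:
    """Union of all minimum spanning trees of the haplotype distance graph.

    Identical sequences collapse into one node with ``multiplicity`` and
    ``members`` attributes. Distinct edge weights are processed in
    increasing order; within a weight class every edge joining components
    that were distinct *before the class opened* is added, then the unions
    are applied - this yields exactly the union of all MSTs.
    """
    if not seqs:
        raise ValueError("need at least one haplotype")
    by_seq: dict[str, list[str]] = {}
    for name, s in seqs.items():
        by_seq.setdefault(s.upper(), []).append(name)
    haps = list(by_seq)
    net = nx.Graph(epsilon=0)
    for i, h in enumerate(haps):
        net.add_node(i, sequence=h, multiplicity=len(by_seq[h]),
                     members=sorted(by_seq[h]))
    if len(haps) == 1:
        return net

    edges = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d, _ = count_differences(haps[i], haps[j])
            edges.append((d, i, j))
    dsu = _DSU(len(haps))
    for w in sorted({e[0] for e in edges}):
        snapshot = [dsu.find(i) for i in range(len(haps))]
        added = []
        for d, i, j in edges:
            if d == w and snapshot[i] != snapshot[j]:
                net.add_edge(i, j, weight=int(d))
                added.append((i, j))
        for i, j in added:
            dsu.union(i, j)
        if len({dsu.find(i) for i in range(len(haps))}) == 1:
            break
    return net
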