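#!/usr/bin/env python
"""Quantify differentiation between arrangements and between continents.

Computes windowed (25 kb) and global Hudson FST for the four contrasts
(SS vs NN within each continent, between continents within each
homokaryote class), inside and outside the called inversion. Then builds
the epsilon = 0 minimum spanning network of marker-region haplotypes.
"""
import argparse
from pathlib import Path

import pandas as pd

from invclines.io_formats import read_vcf
from invclines.popgen_stats import (minimum_spanning_network,
                                    pairwise_divergence, windowed_fst)
from invclines.synthetic_data import simulate_marker_region


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--scan-dir", type=Path, default=Path("results/scan"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/popgen"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    g = read_vcf(args.in_dir / "genotypes.vcf")
    meta = pd.read_csv(args.in_dir / "samples.tsv", sep="\t",
                       index_col="sample")
    kar = pd.read_csv(args.scan_dir / "karyotypes.tsv", sep="\t",
                      index_col="sample")["karyotype"]
    import json
    interval = tuple(json.loads(
        (args.scan_dir / "region_call.json").read_text())["interval"])

    def grp(karyo=None, cont=None):
        keep = meta.index.to_series()
        if karyo:
            keep = keep[kar.loc[keep] == karyo]
        if cont:
            keep = keep[meta.loc[keep, "continent"] == cont]
        return list(keep)

    contrasts = {
        "SS-vs-NN (America)": (grp("SS", "America"), grp("NN", "America")),
        "SS-vs-NN (Europe)": (grp("SS", "Europe"), grp("NN", "Europe")),
        "America-vs-Europe (SS)": (grp("SS", "America"), grp("SS", "Europe")),
        "America-vs-Europe (NN)": (grp("NN", "America"), grp("NN", "Europe")),
    }
    rows, windows = [], []
    for name, (a, b) in contrasts.items():
        inside = windowed_fst(g, a, b, interval=interval)
        chrom = windowed_fst(g, a, b)
        rows.append({"contrast": name, "n_a": len(a), "n_b": len(b),
                     "fst_inside_inversion": inside.fst,
                     "fst_whole_chromosome": chrom.fst})
        windows.append(chrom.windows.assign(contrast=name))
        print(f"{name}: FST inside inversion {inside.fst:.3f}, "
              f"whole chromosome {chrom.fst:.3f}")
    pd.DataFrame(rows).to_csv(args.out_dir / "fst_contrasts.tsv", sep="\t",
                              index=False)
    pd.concat(windows).to_csv(args.out_dir / "fst_windows_25kb.tsv",
                              sep="\t", index=False)

    # haplotype network over the diagnostic marker region, trimmed to 488 bp,
    # with one or two continent-private substitutions within each arrangement
    import numpy as np
    rng = np.random.default_rng(args.seed)
    sim = simulate_marker_region(seed=args.seed)
    s, e = 0, 488

    def mutate(seq, k):
        seq = list(seq)
        for p in rng.choice(len(seq), size=k, replace=False):
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        return "".join(seq)

    haps = {}
    for i in range(4):
        haps[f"S_Am_{i}"] = sim.seq_s[s:e]
        haps[f"N_Am_{i}"] = sim.seq_n[s:e]
    eu_s, eu_n = mutate(sim.seq_s[s:e], 1), mutate(sim.seq_n[s:e], 2)
    for i in range(4):
        haps[f"S_Eu_{i}"] = eu_s
        haps[f"N_Eu_{i}"] = eu_n
    net = minimum_spanning_network(haps)
    dm = pairwise_divergence({"S": sim.seq_s[s:e], "N": sim.seq_n[s:e]})
    edges = pd.DataFrame([
        {"node_a": u, "node_b": v, "steps": w,
         "mult_a": net.nodes[u]["multiplicity"],
         "mult_b": net.nodes[v]["multiplicity"]}
        for u, v, w in net.edges(data="weight")])
    edges.to_csv(args.out_dir / "haplotype_network_edges.tsv", sep="\t",
                 index=False)
    print(f"marker-region haplotypes: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges; S-N divergence "
          f"{dm.counts.loc['S', 'N']} substitutions "
          f"({dm.percent.loc['S', 'N']}%) over 488 bp")


if __name__ == "__main__":
    main()
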