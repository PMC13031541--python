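"""Rule-based design of diagnostic PCR-RFLP assays.

A diagnostic marker is a SNP that (1) lies in a coding region, (2) is fixed
(or nearly fixed) between the two inversion homokaryote groups, and (3)
creates a restriction-enzyme recognition site on exactly one arrangement, so
that karyotypes can be read from digestion fragment patterns on a gel.

Recognition sites are defined on duplex DNA: every scan considers the forward
strand and the reverse complement of the site.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (Enzyme, FeatureSet, GenotypeMatrix, IUPAC_CODES,
                         reverse_complement)

_IUPAC_REGEX = {code: (bases.pop() if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
                for code, bases in ((c, set(s)) for c, s in IUPAC_CODES.items())}


def _site_pattern(site: str) -> re.Pattern:
    # lookahead so overlapping matches are found
    return re.compile("(?=" + "".join(_IUPAC_REGEX[b] for b in site.upper()) + ")")


def site_match_intervals(seq: str, site: str) -> list[tuple[int, int]]:
    """Half-open intervals where ``site`` matches ``seq`` on either strand."""
    seq = seq.upper()
    L = len(site)
    out = [(m.start(), m.start() + L) for m in _site_pattern(site).finditer(seq)]
    rc = reverse_complement(site)
    if rc != site:
        out += [(m.start(), m.start() + L) for m in _site_pattern(rc).finditer(seq)]
    return sorted(set(out))


def in_silico_digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths (5'->3') after complete digestion.

    Cuts at ``cut_offset`` into each forward-strand match; for a match of the
    reverse complement of a non-palindromic site the cut sits mirrored at
    ``len(site) - cut_offset``. Fragment lengths always sum to the input
    length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    L = len(enzyme.site)
    cuts: set[int] = set()
    for m in _site_pattern(enzyme.site).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    rc = reverse_complement(enzyme.site)
    if rc != enzyme.site:
        for m in _site_pattern(rc).finditer(seq):
            cuts.add(m.start() + L - enzyme.cut_offset)
    cuts = {c for c in cuts if 0 < c < len(seq)}
    bounds = [0] + sorted(cuts) + [len(seq)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def candidate_diagnostic_snps(g: GenotypeMatrix, karyotypes: Mapping[str, str],
                              features: FeatureSet,
                              min_diff: float = 0.99) -> pd.DataFrame:
    """SNPs inside a CDS with |freq_alt(SS) - freq_alt(NN)| >= ``min_diff``.

    Frequencies are computed over non-missing calls of the homokaryote
    groups. Returns one row per retained SNP with per-group frequencies.
    """
    ss = [s for s in g.samples if karyotypes.get(s) == "SS"]
    nn = [s for s in g.samples if karyotypes.get(s) == "NN"]
    if len(ss) < 2 or len(nn) < 2:
        raise ValueError("need >= 2 SS and >= 2 NN samples")
    p_ss, n_ss = g.allele_frequencies(g.sample_index(ss))
    p_nn, n_nn = g.allele_frequencies(g.sample_index(nn))
    with np.errstate(invalid="ignore"):
        diff = np.abs(p_ss - p_nn)
    usable = (n_ss > 0) & (n_nn > 0) & (diff >= min_diff)

    cds = features.of_type("CDS")
    in_cds = np.zeros(g.n_sites, dtype=bool)
    cds_id = np.full(g.n_sites, "", dtype=object)
    pos = g.sites["pos"].to_numpy()
    chrom = g.sites["chrom"].to_numpy()
    for _, f in cds.iterrows():
        hit = (chrom == f["chrom"]) & (pos >= f["start"]) & (pos < f["end"])
        cds_id[hit & ~in_cds] = f["id"]
        in_cds |= hit

    keep = usable & in_cds
    out = g.sites.loc[keep, ["chrom", "pos", "ref", "alt"]].copy()
    out["freq_ss"] = p_ss[keep]
    out["freq_nn"] = p_nn[keep]
    out["diff"] = diff[keep]
    out["cds_id"] = cds_id[keep]
    out["site_index"] = np.flatnonzero(keep)
    return out.reset_index(drop=True)


def restriction_contrast(reference: str,
                         snp: tuple[int, str, str],
                         enzymes: Sequence[Enzyme],
                         flank: int = 30) -> list[tuple[Enzyme, str]]:
    """Enzymes whose recognition site overlaps the SNP on exactly one allele.

    ``snp`` is (0-based position, allele A, allele B). Returns
    ``(enzyme, cut_allele)`` pairs, where ``cut_allele`` is the base whose
    local sequence is cut. A site match "overlaps" the SNP when its interval
    contains the SNP position - distant sites never produce a contrast.
    """
    pos, a1, a2 = snp
    if not 0 <= pos < len(reference):
        raise ValueError("SNP outside reference")
    max_site = max(len(e.site) for e in enzymes) if enzymes else 0
    if flank < max_site - 1:
        raise ValueError(f"flank {flank} too small for sites up to {max_site} bp")
    if pos - flank < 0 or pos + flank + 1 > len(reference):
        raise ValueError("SNP too close to contig edge for requested flank")
    window = reference[pos - flank:pos + flank + 1].upper()
    local = flank  # SNP offset inside the window
    out = []
    for enz in enzymes:
        hits = {}
        for allele in (a1, a2):
            sub = window[:local] + allele.upper() + window[local + 1:]
            hits[allele] = any(s <= local < e
                               for s, e in site_match_intervals(sub, enz.site))
        if hits[a1] != hits[a2]:
            out.append((enz, a1 if hits[a1] else a2))
    return out


@dataclass
class MarkerCandidate:
    """A diagnostic SNP + enzyme + amplicon with predicted gel patterns."""

    chrom: str
    pos: int                        # 0-based
    s_allele: str
    n_allele: str
    cds_id: str
    enzyme: Enzyme
    cut_arrangement: str            # "S" or "N"
    amplicon: tuple[int, int]       # half-open, on the reference
    fragments: dict[str, list[int]]  # per karyotype SS/SN/NN
    freq_ss: float
    freq_nn: float
    diff: float
    distinguishability: int         # min pairwise fragment-length difference
    linked_snps: list[int] = field(default_factory=list)


def _min_fragment_gap(fragments: dict[str, list[int]]) -> int:
    lengths = sorted({f for pat in fragments.values() for f in pat})
    if len(lengths) < 2:
        return 0
    return min(b - a for a, b in zip(lengths[:-1], lengths[1:]))


def design_markers(g: GenotypeMatrix, karyotypes: Mapping[str, str],
                   reference: Mapping[str, str], features: FeatureSet,
                   enzymes: Sequence[Enzyme],
                   amplicon_length: int = 667,
                   min_diff: float = 0.99,
                   gel_resolution: int = 50,
                   flank: int = 30) -> list[MarkerCandidate]:
    """Compose the three design rules into ranked marker candidates.

    Candidates are ranked by homokaryote allele-frequency difference, then by
    whether all predicted fragments are separable at ``gel_resolution`` bp,
    then by the separation itself.
    """
    snps = candidate_diagnostic_snps(g, karyotypes, features, min_diff)
    candidates: list[MarkerCandidate] = []
    for row in snps.itertuples():
        ref_seq = reference.get(row.chrom)
        if ref_seq is None:
            continue
        # S allele = the allele at high frequency in the SS group
        s_allele = row.alt if row.freq_ss > row.freq_nn else row.ref
        n_allele = row.ref if s_allele == row.alt else row.alt
        try:
            contrasts = restriction_contrast(ref_seq, (row.pos, s_allele, n_allele),
                                             enzymes, flank)
        except ValueError:
            continue  # contig edge
        for enz, cut_allele in contrasts:
            half = amplicon_length // 2
            start = min(max(0, row.pos - half), max(0, len(ref_seq) - amplicon_length))
            end = min(len(ref_seq), start + amplicon_length)
            amp = {}
            for label, allele in (("S", s_allele), ("N", n_allele)):
                sub = (ref_seq[start:row.pos] + allele
                       + ref_seq[row.pos + 1:end]).upper()
                amp[label] = in_silico_digest(sub, enz)
            cut_arr = "S" if cut_allele == s_allele else "N"
            frag = {
                "SS": amp["S"], "NN": amp["N"],
                "SN": sorted(set(amp["S"]) | set(amp["N"])),
            }
            # other candidate SNPs inside the same recognition-site match
            off = row.pos - flank
            cut_window = (ref_seq[off:row.pos] + cut_allele
                          + ref_seq[row.pos + 1:row.pos + flank + 1]).upper()
            spans = [(s + off, e + off)
                     for s, e in site_match_intervals(cut_window, enz.site)
                     if s + off <= row.pos < e + off]
            linked = [int(p) for p in snps["pos"]
                      if p != row.pos and any(s <= p < e for s, e in spans)]
            candidates.append(MarkerCandidate(
                row.chrom, int(row.pos), s_allele, n_allele, row.cds_id, enz,
                cut_arr, (start, end), frag, float(row.freq_ss),
                float(row.freq_nn), float(row.diff), _min_fragment_gap(frag),
                linked))
    candidates.sort(key=lambda c: (-c.diff,
                                   -(c.distinguishability >= gel_resolution),
                                   -c.distinguishability, c.pos))
    return candidates


@dataclass
class ConcordanceResult:
    """Agreement between marker-based and PCA-based karyotypes."""

    n_compared: int
    n_concordant: int
    rate: int                       # percent, nearest integer
    discordant: list[str]


def concordance(marker_karyotypes: Mapping[str, str],
                pca_karyotypes: Mapping[str, str]) -> ConcordanceResult:
    """Concordance rate (%) over samples present in both call sets."""
    shared = sorted(set(marker_karyotypes) & set(pca_karyotypes))
    if not shared:
        raise ValueError("no overlapping samples")
    disc = [s for s in shared if marker_karyotypes[s] != pca_karyotypes[s]]
    n = len(shared)
    n_conc = n - len(disc)
    return ConcordanceResult(n, n_conc, int(round(100 * n_conc / n)), disc)
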