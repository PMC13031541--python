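import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invclines.io_formats import Enzyme, FeatureSet, GenotypeMatrix
from invclines.marker_design import (candidate_diagnostic_snps, concordance,
                                     design_markers, in_silico_digest,
                                     restriction_contrast,
                                     site_match_intervals)
from invclines.synthetic_data import simulate_marker_region

ECORI = Enzyme("EcoRI", "GAATTC", 1)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def test_digest_cuts_after_the_g():
    assert in_silico_digest("AAAGAATTCAAA", ECORI) == [4, 8]


def test_digest_without_site_returns_whole_sequence():
    assert in_silico_digest("ACACACAC", ECORI) == [8]


def test_digest_reverse_strand_site_of_nonpalindromic_enzyme():
    # site only as reverse complement on the top strand: still cut
    enz = Enzyme("toy", "GACGTT", 2)  # rc = AACGTC
    seq = "TTTTAACGTCTTTT"
    frags = in_silico_digest(seq, enz)
    assert len(frags) == 2 and sum(frags) == len(seq)
    # mirrored offset: cut at match_start + len - offset = 4 + 6 - 2
    assert frags == [8, 6]


def test_digest_degenerate_site():
    enz = Enzyme("toy2", "GRATTC", 1)  # R = A or G
    assert len(in_silico_digest("AAGAATTCAA", enz)) >= 2
    assert len(in_silico_digest("AAGGATTCAA", enz)) >= 2


@given(st.text(alphabet="ACGT", min_size=1, max_size=300),
       st.sampled_from(["GAATTC", "TTAA", "AGCT", "GGCC", "GACGTT"]),
       st.integers(0, 3))
@settings(max_examples=150, deadline=None)
def test_digest_fragments_sum_to_length(seq, site, offset):
    enz = Enzyme("x", site, min(offset, len(site)))
    frags = in_silico_digest(seq, enz)
    assert sum(frags) == len(seq)
    assert all(f > 0 for f in frags)


def test_overlapping_sites_all_found():
    assert site_match_intervals("TTAATTAA", "TTAA") == [(0, 4), (4, 8)]
    assert site_match_intervals("ATTAATTAAT", "TTAA") == [(1, 5), (5, 9)]


# ---------------------------------------------------------------------------
# candidate SNPs
# ---------------------------------------------------------------------------

def _tiny_dataset():
    """Six samples, four sites; site 1 is karyotype-fixed and inside a CDS."""
    samples = ["a1", "a2", "h1", "h2", "b1", "b2"]
    kar = {"a1": "SS", "a2": "SS", "h1": "SN", "h2": "SN",
           "b1": "NN", "b2": "NN"}
    #          bg    diag  bg    outside-CDS-diag
    dosages = np.array([
        [0, 0, 1, 0],
        [1, 0, 0, 0],
        [0, 1, 1, 1],
        [1, 1, 2, 1],
        [0, 2, 1, 2],
        [1, 2, 2, 2],
    ])
    sites = pd.DataFrame({"chrom": "c", "pos": [10, 50, 90, 200],
                          "ref": "A", "alt": "T"})
    feats = FeatureSet(pd.DataFrame([
        {"chrom": "c", "start": 0, "end": 100, "type": "CDS", "id": "cds1",
         "strand": "+"}]))
    return GenotypeMatrix(samples, sites, dosages), kar, feats


def test_candidates_respect_both_rules():
    g, kar, feats = _tiny_dataset()
    out = candidate_diagnostic_snps(g, kar, feats)
    assert list(out["pos"]) == [50]  # fixed AND in CDS; pos 200 is outside
    assert out.loc[0, "diff"] == pytest.approx(1.0)


def test_candidates_match_brute_force_on_synthetic_region():
    sim = simulate_marker_region(seed=2, background_rate=0.02)
    g, kar, feats = sim.genotypes, sim.karyotypes, sim.features
    out = candidate_diagnostic_snps(g, kar, feats)
    ss = [i for i, s in enumerate(g.samples) if kar[s] == "SS"]
    nn = [i for i, s in enumerate(g.samples) if kar[s] == "NN"]
    cds = feats.of_type("CDS").iloc[0]
    expected = []
    for j in range(g.n_sites):
        f1 = g.dosages[ss, j].mean() / 2
        f2 = g.dosages[nn, j].mean() / 2
        pos = g.sites.loc[j, "pos"]
        if abs(f1 - f2) >= 0.99 and cds["start"] <= pos < cds["end"]:
            expected.append(pos)
    assert list(out["pos"]) == expected


def test_candidates_require_homokaryotes():
    g, kar, feats = _tiny_dataset()
    kar = dict.fromkeys(kar, "SN")
    with pytest.raises(ValueError):
        candidate_diagnostic_snps(g, kar, feats)


# ---------------------------------------------------------------------------
# restriction contrast
# ---------------------------------------------------------------------------

def test_contrast_reports_the_cut_allele():
    ref = "T" * 30 + "GTATTC" + "T" * 30  # A at snp makes GAATTC
    snp = (31, "A", "T")
    out = restriction_contrast(ref, snp, [ECORI], flank=20)
    assert out == [(ECORI, "A")]


def test_contrast_empty_when_no_site_possible():
    ref = "T" * 61
    assert restriction_contrast(ref, (30, "A", "C"), [ECORI], flank=20) == []


def test_contrast_excludes_site_not_overlapping_snp():
    # a constitutive EcoRI site sits away from the SNP; both alleles cut
    ref = "T" * 10 + "GAATTC" + "T" * 20 + "A" + "T" * 20
    out = restriction_contrast(ref, (37, "A", "C"), [ECORI], flank=15)
    assert out == []


def test_contrast_edge_errors():
    with pytest.raises(ValueError):
        restriction_contrast("ACGTACGT", (1, "A", "C"), [ECORI], flank=6)
    with pytest.raises(ValueError):
        restriction_contrast("A" * 100, (50, "A", "C"), [ECORI], flank=2)


# ---------------------------------------------------------------------------
# full design + concordance
# ---------------------------------------------------------------------------

def test_design_recovers_planted_marker(enzymes):
    sim = simulate_marker_region(seed=5)
    cands = design_markers(sim.genotypes, sim.karyotypes, sim.reference,
                           sim.features, enzymes,
                           amplicon_length=sim.amplicon_length)
    top = cands[0]
    assert (top.pos, top.enzyme.name) == (sim.snp_pos, sim.enzyme.name)
    assert top.cut_arrangement == "S"
    assert top.amplicon[1] - top.amplicon[0] == 667
    assert sum(top.fragments["SS"]) == 667
    assert top.fragments["NN"] == [667]
    # heterokaryote lane = union of the homokaryote lanes
    assert top.fragments["SN"] == sorted(set(top.fragments["SS"])
                                         | set(top.fragments["NN"]))
    # composition property: every candidate passed the frequency filter
    snps = candidate_diagnostic_snps(sim.genotypes, sim.karyotypes,
                                     sim.features)
    assert {c.pos for c in cands} <= set(snps["pos"])


def test_design_empty_without_cds(enzymes):
    sim = simulate_marker_region(seed=6)
    assert design_markers(sim.genotypes, sim.karyotypes, sim.reference,
                          FeatureSet(), enzymes) == []


@pytest.mark.parametrize("n,conc,rate", [(103, 102, 99), (38, 32, 84),
                                         (10, 10, 100)])
def test_concordance_rounds_to_integer_percent(n, conc, rate):
    marker = {f"s{i}": "SS" for i in range(n)}
    pca = dict(marker)
    for i in range(n - conc):
        pca[f"s{i}"] = "NN"
    res = concordance(marker, pca)
    assert (res.n_compared, res.n_concordant, res.rate) == (n, conc, rate)
    assert len(res.discordant) == n - conc


def test_concordance_requires_overlap():
    with pytest.raises(ValueError):
        concordance({"a": "SS"}, {"b": "SS"})
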