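"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates a two-continent metapopulation carrying a polymorphic
chromosomal inversion:

* background (collinear) sites are differentiated between continents under a
  Balding-Nichols model with parameter ``f_bg`` (the expected Hudson FST);
* inside the inversion, the two arrangements S and N behave as two deeply
  diverged non-recombining haplotype pools: a fraction ``d_inv`` of sites is
  fixed-different between arrangements, a fraction ``mu_poly`` of the rest is
  polymorphic but shared, and the remainder is monomorphic;
* karyotypes at each location follow Hardy-Weinberg proportions with
  p_S = logistic(beta0 + beta1 * latitude), a logistic latitudinal cline.

Haplotypes are drawn i.i.d. per site given arrangement/continent frequencies
(no within-pool linkage disequilibrium) - enough to reproduce the local-PCA
three-cluster signature and the FST contrasts, and documented as a
simplification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import Enzyme, FeatureSet, GenotypeMatrix, LocationCounts

#: bounds of the uniform law for shared/background polymorphic frequencies
FREQ_LOW, FREQ_HIGH = 0.05, 0.95

KARYOTYPES = ("SS", "SN", "NN")


@dataclass
class SimulationConfig:
    """Study conditions for the whole-genome inversion simulation.

    Defaults are the conditions the analyses were designed around: six
    locations alternating between two continents along a 49-69 degree
    latitudinal span, 40 diploids each, a 4 Mb inversion on an 8 Mb
    chromosome, cline coefficients equal to the European fit, background
    differentiation f_bg = 0.13 and arrangement divergence targeting
    FST ~ 0.63 between homokaryote groups.
    """

    n_locations: int = 6
    latitudes: tuple[float, ...] = (49.0, 53.0, 57.0, 61.0, 65.0, 69.0)
    samples_per_location: int = 40
    n_sites: int = 4000
    chrom_length: int = 8_000_000
    inversion: tuple[int, int] = (1_000_000, 5_000_000)
    beta0: float = 6.23
    beta1: float = -0.1064
    f_bg: float = 0.13
    d_inv: float = 0.3
    mu_poly: float = 0.7
    chrom: str = "chr4"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f_bg < 1:
            raise ValueError("f_bg must be in [0, 1)")
        if not 0 <= self.d_inv <= 1:
            raise ValueError("d_inv must be in [0, 1]")
        if not 0 <= self.mu_poly <= 1:
            raise ValueError("mu_poly must be in [0, 1]")
        s, e = self.inversion
        if not (0 <= s < e <= self.chrom_length):
            raise ValueError("inversion interval outside chromosome")
        if not np.isfinite(self.beta1):
            raise ValueError("beta1 must be finite")
        if len(self.latitudes) != self.n_locations:
            raise ValueError("need one latitude per location")

    @property
    def continents(self) -> tuple[str, ...]:
        """Locations alternate between the two continents."""
        return tuple("America" if i % 2 == 0 else "Europe"
                     for i in range(self.n_locations))


def expected_inversion_fst(config: SimulationConfig) -> float:
    """Analytic ratio-of-averages Hudson FST between SS and NN haplotype
    pools inside the inversion implied by the generator's site-class law.

    Fixed-difference sites contribute numerator = denominator = 1; shared
    polymorphic sites contribute ~0 numerator and 2 E[p(1-p)] denominator
    with p ~ U(FREQ_LOW, FREQ_HIGH); monomorphic sites contribute nothing.
    """
    d, mu = config.d_inv, config.mu_poly
    mean_p = (FREQ_LOW + FREQ_HIGH) / 2
    var_p = (FREQ_HIGH - FREQ_LOW) ** 2 / 12
    het = 2 * (mean_p - (var_p + mean_p ** 2))
    denom = d + (1 - d) * mu * het
    return d / denom if denom > 0 else float("nan")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated dataset."""

    karyotypes: dict[str, str]
    inversion: tuple[int, int]
    beta0: float
    beta1: float
    site_class: np.ndarray          # "background" | "fixed" | "shared" | "mono"
    freq_s: np.ndarray              # alt frequency on the S arrangement
    freq_n: np.ndarray              # alt frequency on the N arrangement
    locations: pd.DataFrame = field(default_factory=pd.DataFrame)


def _draw_karyotypes(rng: np.random.Generator, n: int, p_s: float) -> np.ndarray:
    """Per-individual arrangement pairs under HWE: two independent draws."""
    return rng.binomial(1, 1 - p_s, size=(n, 2))  # 0 = S, 1 = N


def simulate_inversion_dataset(config: SimulationConfig
                               ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate genotypes for a chromosome carrying one polymorphic inversion."""
    ss = np.random.SeedSequence(config.seed)
    rng_sites, rng_freqs, rng_geno = (np.random.default_rng(s)
                                      for s in ss.spawn(3))

    positions = np.sort(rng_sites.choice(config.chrom_length,
                                         size=config.n_sites, replace=False))
    inv_s, inv_e = config.inversion
    inside = (positions >= inv_s) & (positions < inv_e)
    if inside.sum() < 2:
        raise ValueError("inversion interval contains < 2 sites")

    n_sites = config.n_sites
    site_class = np.full(n_sites, "background", dtype=object)
    u = rng_freqs.random(n_sites)
    fixed = inside & (u < config.d_inv)
    shared = inside & ~fixed & (u < config.d_inv + (1 - config.d_inv) * config.mu_poly)
    mono = inside & ~fixed & ~shared
    site_class[fixed] = "fixed"
    site_class[shared] = "shared"
    site_class[mono] = "mono"

    # arrangement-specific alt frequencies inside the inversion
    freq_s = np.zeros(n_sites)
    freq_n = np.zeros(n_sites)
    s_carries_alt = rng_freqs.random(n_sites) < 0.5
    freq_s[fixed] = np.where(s_carries_alt[fixed], 1.0, 0.0)
    freq_n[fixed] = 1.0 - freq_s[fixed]
    p_shared = rng_freqs.uniform(FREQ_LOW, FREQ_HIGH, size=n_sites)
    freq_s[shared] = p_shared[shared]
    freq_n[shared] = p_shared[shared]

    # continent-specific background frequencies (Balding-Nichols)
    outside = ~inside
    p0 = rng_freqs.uniform(FREQ_LOW, FREQ_HIGH, size=n_sites)
    cont_freq = {}
    for cont in ("America", "Europe"):
        if config.f_bg > 0:
            a = p0 * (1 - config.f_bg) / config.f_bg
            b = (1 - p0) * (1 - config.f_bg) / config.f_bg
            cont_freq[cont] = rng_freqs.beta(a, b)
        else:
            cont_freq[cont] = p0.copy()

    samples: list[str] = []
    meta_rows = []
    karyotypes: dict[str, str] = {}
    dosage_rows = []
    continents = config.continents
    loc_table = []
    for li, (lat, cont) in enumerate(zip(config.latitudes, continents)):
        loc = f"L{li + 1}"
        p_s = float(expit(config.beta0 + config.beta1 * lat))
        arr = _draw_karyotypes(rng_geno, config.samples_per_location, p_s)
        loc_table.append({"location": loc, "latitude": lat, "continent": cont,
                          "p_s": p_s})
        for i in range(config.samples_per_location):
            name = f"{loc}_{i:02d}"
            samples.append(name)
            n_count = arr[i].sum()
            karyotypes[name] = ("SS", "SN", "NN")[n_count]
            meta_rows.append({"sample": name, "continent": cont,
                              "location": loc, "latitude": lat})
            # background: two alleles from the continental pool
            dos = rng_geno.binomial(2, cont_freq[cont]).astype(np.int8)
            # inversion: one haplotype per arrangement copy
            hap = np.zeros(n_sites, dtype=np.int8)
            for copy in arr[i]:
                f = freq_n if copy else freq_s
                hap += (rng_geno.random(n_sites) < f).astype(np.int8)
            dos[inside] = hap[inside]
            dosage_rows.append(dos)

    sites = pd.DataFrame({
        "chrom": config.chrom, "pos": positions,
        "ref": "A", "alt": "T",
    })
    meta = pd.DataFrame(meta_rows).set_index("sample")
    g = GenotypeMatrix(samples, sites, np.array(dosage_rows), meta)
    truth = TruthRecord(karyotypes, config.inversion, config.beta0, config.beta1,
                        site_class, freq_s, freq_n, pd.DataFrame(loc_table))
    return g, truth


def simulate_cline_counts(beta0: float, beta1: float,
                          latitudes: "np.typing.ArrayLike",
                          n_per_location: int, seed: int,
                          temperatures: "np.typing.ArrayLike | None" = None
                          ) -> list[LocationCounts]:
    """Multinomial karyotype counts under HWE along a logistic cline.

    If ``temperatures`` is not given, an affine lapse-rate proxy
    ``25 - 0.3 * latitude`` fills the temperature column.
    """
    if n_per_location < 1:
        raise ValueError("need n >= 1 per location")
    lats = np.asarray(latitudes, dtype=float)
    temps = (np.asarray(temperatures, dtype=float) if temperatures is not None
             else 25.0 - 0.3 * lats)
    rng = np.random.default_rng(seed)
    out = []
    for i, lat in enumerate(lats):
        p = float(expit(beta0 + beta1 * lat))
        probs = (p * p, 2 * p * (1 - p), (1 - p) * (1 - p))
        n_ss, n_sn, n_nn = rng.multinomial(n_per_location, probs)
        out.append(LocationCounts(f"L{i + 1}", float(lat), 0.0, float(temps[i]),
                                  int(n_ss), int(n_sn), int(n_nn)))
    return out


@dataclass
class MarkerRegionSim:
    """A small coding region with one planted diagnostic PCR-RFLP site."""

    reference: dict[str, str]       # single contig, the S arrangement sequence
    features: FeatureSet
    seq_s: str
    seq_n: str
    genotypes: GenotypeMatrix
    karyotypes: dict[str, str]
    snp_pos: int                    # 0-based position of the diagnostic SNP
    enzyme: Enzyme
    amplicon_length: int


def _substitute(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def simulate_marker_region(length: int = 1200,
                           snp_pos: int | None = None,
                           enzyme: Enzyme = Enzyme("EcoRI", "GAATTC", 1),
                           site_offset: int = 2,
                           amplicon_length: int = 667,
                           background_rate: float = 0.01,
                           n_per_karyotype: int = 6,
                           seed: int = 0,
                           chrom: str = "contig1",
                           catalogue: "list[Enzyme] | None" = None
                           ) -> MarkerRegionSim:
    """Plant a diagnostic SNP: S carries the recognition site, N breaks it.

    The region carries one CDS of ``amplicon_length`` bp centred on the SNP,
    plus background fixed differences between arrangements at
    ``background_rate``. Candidate background positions that would create a
    restriction contrast for any enzyme in ``catalogue`` (default: the
    packaged catalogue) are redrawn, so the planted SNP is the region's
    unique diagnostic site.
    """
    from .io_formats import IUPAC_CODES, load_default_enzymes
    from .marker_design import restriction_contrast, site_match_intervals

    rng = np.random.default_rng(seed)
    site = enzyme.site
    if snp_pos is None:
        snp_pos = length // 2
    site_start = snp_pos - site_offset
    if site_start < 0 or site_start + len(site) > length:
        raise ValueError("enzyme site does not fit at the diagnostic position")
    if not 0 <= site_offset < len(site):
        raise ValueError("site_offset outside recognition site")
    if catalogue is None:
        catalogue = load_default_enzymes()
    if enzyme.name not in {e.name for e in catalogue}:
        catalogue = list(catalogue) + [enzyme]
    flank = max(len(e.site) for e in catalogue)

    bases = np.array(list("ACGT"))
    site_bases = IUPAC_CODES[site[site_offset]]
    break_choices = [b for b in "ACGT" if b not in site_bases]
    if not break_choices:
        raise ValueError("degenerate site position cannot be broken by a SNP")

    def contrasts_at(seq: str, pos: int, a1: str, a2: str) -> list:
        if pos - flank < 0 or pos + flank + 1 > len(seq):
            return [None]  # too close to the edge: treat as unusable
        return restriction_contrast(seq, (pos, a1, a2), catalogue, flank)

    for _ in range(500):
        seq = "".join(rng.choice(bases, size=length))
        seq_s = seq[:site_start] + site + seq[site_start + len(site):]
        n_base = str(rng.choice(break_choices))
        seq_n = _substitute(seq_s, snp_pos, n_base)
        # S must carry exactly the planted site; N must carry none; and the
        # planted enzyme must be the only catalogue contrast at the SNP
        hits_s = site_match_intervals(seq_s, site)
        if hits_s != [(site_start, site_start + len(site))] or \
                site_match_intervals(seq_n, site):
            continue
        hits = contrasts_at(seq_s, snp_pos, seq_s[snp_pos], n_base)
        if len(hits) == 1 and hits[0] is not None and \
                hits[0][0].name == enzyme.name:
            break
    else:
        raise RuntimeError("could not place a clean diagnostic region")

    # background fixed differences between arrangements (outside the site)
    n_bg = int(rng.binomial(length, background_rate))
    bg_positions: list[int] = []
    tries = 0
    while len(bg_positions) < n_bg and tries < 50 * max(n_bg, 1):
        tries += 1
        p = int(rng.integers(flank, length - flank))
        if abs(p - snp_pos) <= len(site) or p in bg_positions:
            continue
        new = str(rng.choice([b for b in "ACGT" if b != seq_n[p]]))
        if contrasts_at(seq_s, p, seq_s[p], new):
            continue  # would create a second contrast somewhere in the catalogue
        seq_n = _substitute(seq_n, p, new)
        bg_positions.append(p)

    cds_start = max(0, min(snp_pos - amplicon_length // 2, length - amplicon_length))
    cds_end = min(length, cds_start + amplicon_length)
    features = FeatureSet(pd.DataFrame([{
        "chrom": chrom, "start": cds_start, "end": cds_end,
        "type": "CDS", "id": "CDS1", "strand": "+",
    }]))

    # genotype matrix over all S/N differing positions
    diff_pos = sorted([snp_pos] + bg_positions)
    samples, karyos, rows = [], {}, []
    for kar, n_copies in (("SS", 0), ("SN", 1), ("NN", 2)):
        for i in range(n_per_karyotype):
            name = f"{kar}_{i:02d}"
            samples.append(name)
            karyos[name] = kar
            # dosage of the N-arrangement base at each differing position
            rows.append(np.full(len(diff_pos), n_copies, dtype=np.int8))
    sites = pd.DataFrame({
        "chrom": chrom, "pos": diff_pos,
        "ref": [seq_s[p] for p in diff_pos],
        "alt": [seq_n[p] for p in diff_pos],
    })
    g = GenotypeMatrix(samples, sites, np.array(rows))
    return MarkerRegionSim({chrom: seq_s}, features, seq_s, seq_n, g, karyos,
                           snp_pos, enzyme, amplicon_length)


def simulate_viability_experiment(a: float, b: float, c: float,
                                  temperatures: "np.typing.ArrayLike",
                                  eggs_per_replicate: int = 100,
                                  replicates: int = 6,
                                  seed: int = 0,
                                  line: str = "line1",
                                  continent: str = "America",
                                  karyotype: str = "SS") -> pd.DataFrame:
    """Binomial egg-to-adult survival following a quadratic thermal curve.

    The quadratic a*T^2 + b*T + c is clipped to [0, 1] before use as the
    binomial success probability. One row per replicate batch.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in np.asarray(temperatures, dtype=float):
        p = float(np.clip(a * t * t + b * t + c, 0.0, 1.0))
        for r in range(replicates):
            adults = int(rng.binomial(eggs_per_replicate, p))
            rows.append({"line": line, "karyotype": karyotype,
                         "continent": continent, "temperature": t,
                         "replicate": r + 1, "eggs": eggs_per_replicate,
                         "adults": adults})
    return pd.DataFrame(rows)
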