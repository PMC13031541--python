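"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally. GFF3 and VCF use
1-based conventions; the conversion happens here, at the boundary, and nowhere
else. SNP positions stored in :class:`GenotypeMatrix` are 0-based.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING = -1

IUPAC_CODES = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EmptyDataError(ValueError):
    """Raised when an input yields no usable records."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coordinate conversions
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GFF3/VCF) -> 0-based half-open."""
    if end < start:
        raise ValueError(f"feature end {end} < start {start}")
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive. Inverse of :func:`gff_to_internal`."""
    return start + 1, end


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into internal coordinates."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region)
    if m is None:
        raise ValueError(f"malformed region string: {region!r}")
    chrom = m.group(1)
    start, end = int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    s, e = gff_to_internal(start, end)
    return chrom, s, e


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Hard-called diploid genotypes: individuals x biallelic SNP sites.

    ``dosages`` counts alternate alleles (0/1/2); :data:`MISSING` marks a
    missing call. ``sites`` has columns chrom, pos (0-based), ref, alt.
    ``sample_meta`` (optional) is indexed by sample with columns continent,
    location, latitude.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(self.samples) < 1 or len(self.sites) < 1:
            raise EmptyDataError("GenotypeMatrix needs >= 1 sample and >= 1 site")
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage matrix shape does not match samples x sites")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2,missing}")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=int)

    def site_mask(self, chrom: str | None = None, start: int | None = None,
                  end: int | None = None) -> np.ndarray:
        """Boolean mask over sites for an internal half-open interval."""
        mask = np.ones(self.n_sites, dtype=bool)
        if chrom is not None:
            mask &= (self.sites["chrom"] == chrom).to_numpy()
        pos = self.sites["pos"].to_numpy()
        if start is not None:
            mask &= pos >= start
        if end is not None:
            mask &= pos < end
        return mask

    def allele_frequencies(self, sample_idx: np.ndarray | None = None,
                           site_mask: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele frequency and non-missing allele count per site.

        Missing calls are ignored; sites with no calls get frequency nan.
        """
        D = self.dosages
        if sample_idx is not None:
            D = D[sample_idx]
        if site_mask is not None:
            D = D[:, site_mask]
        valid = D != MISSING
        n_alleles = 2 * valid.sum(axis=0)
        alt = np.where(valid, D, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return p, n_alleles

    def heterozygosity(self, sample_idx: np.ndarray | None = None,
                       site_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-sample observed heterozygosity (fraction of het calls)."""
        D = self.dosages
        if sample_idx is not None:
            D = D[sample_idx]
        if site_mask is not None:
            D = D[:, site_mask]
        valid = (D != MISSING).sum(axis=1)
        het = (D == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid > 0, het / np.maximum(valid, 1), np.nan)


@dataclass
class FeatureSet:
    """Flat set of genomic features (internal 0-based half-open coordinates)."""

    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "type", "id", "strand"]))

    def __post_init__(self) -> None:
        if len(self.features) and (self.features["end"] < self.features["start"]).any():
            raise ValueError("feature end < start")

    def of_type(self, ftype: str) -> pd.DataFrame:
        return self.features[self.features["type"] == ftype]

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and cut offset within it.

    ``cut_offset`` is the number of bases 5' of the cut on the top strand
    (EcoRI G^AATTC has offset 1).
    """

    name: str
    site: str
    cut_offset: int = 1

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError(f"recognition site {site!r} shorter than 4 bp")
        if any(b not in IUPAC_CODES for b in site):
            raise ValueError(f"non-IUPAC character in site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut offset outside recognition site")
        object.__setattr__(self, "site", site)


@dataclass(frozen=True)
class LocationCounts:
    """One sampling location: coordinates, climate, and karyotype counts."""

    location: str
    latitude: float
    longitude: float
    temperature: float
    n_ss: int
    n_sn: int
    n_nn: int

    def __post_init__(self) -> None:
        for n in (self.n_ss, self.n_sn, self.n_nn):
            if n < 0 or int(n) != n:
                raise ValueError("karyotype counts must be non-negative integers")
        if self.n_ss + self.n_sn + self.n_nn < 1:
            raise ValueError("at least one individual required per location")

    @property
    def n(self) -> int:
        return self.n_ss + self.n_sn + self.n_nn


def filter_sites(g: GenotypeMatrix, maf: float = 0.05,
                 max_missing: float = 0.2) -> GenotypeMatrix:
    """Site QC: keep sites with minor-allele frequency >= ``maf`` and a
    missing-call fraction <= ``max_missing``."""
    p, n = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        folded = np.minimum(p, 1 - p)
    miss = (g.dosages == MISSING).mean(axis=0)
    keep = (n > 0) & (folded >= maf) & (miss <= max_missing)
    if not keep.any():
        raise EmptyDataError("no sites left after QC filtering")
    return GenotypeMatrix(list(g.samples),
                          g.sites.loc[keep].reset_index(drop=True),
                          g.dosages[:, keep], g.sample_meta)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read hard GT calls from a VCF into a dosage matrix.

    Only biallelic SNPs are retained; skipped records are counted and logged.
    ``region`` uses 1-based inclusive ``chrom:start-end`` syntax.
    """
    from cyvcf2 import VCF

    want = parse_region(region) if region is not None else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts = [], [], [], []
    rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        pos0 = v.POS - 1
        if want is not None:
            chrom, s, e = want
            if v.CHROM != chrom or not (s <= pos0 < e):
                continue
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a = g[:-1]
            if len(a) >= 2 and a[0] >= 0 and a[1] >= 0:
                dos[i] = a[0] + a[1]
        chroms.append(v.CHROM)
        positions.append(pos0)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyDataError(f"no biallelic SNPs found in {path}"
                             + (f" region {region}" if region else ""))
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    return GenotypeMatrix(samples, sites, np.array(rows).T)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF (positions converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j in range(g.n_sites):
            row = g.sites.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered ``{name: SEQUENCE}``; names are the first token."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise EmptyDataError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = ["chrom", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def read_gff3(path, types: tuple[str, ...] = ("gene", "CDS")) -> FeatureSet:
    """Read GFF3 rows of the requested types (coordinates -> internal)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_GFF_COLS, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return FeatureSet()
    if df.empty:
        return FeatureSet()
    df = df[df["type"].isin(types)].copy()
    if (df["end"] < df["start"]).any():
        raise ValueError("GFF3 row with end < start")
    ids = df["attributes"].str.extract(r"ID=([^;]+)", expand=False).fillna("")
    starts = df["start"].astype(int) - 1
    feats = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(), "start": starts.to_numpy(),
        "end": df["end"].astype(int).to_numpy(), "type": df["type"].to_numpy(),
        "id": ids.to_numpy(), "strand": df["strand"].to_numpy(),
    }).reset_index(drop=True)
    return FeatureSet(feats)


def write_gff3(fs: FeatureSet, path, source: str = "invclines") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, f in fs.features.iterrows():
            start1, end1 = internal_to_gff(int(f["start"]), int(f["end"]))
            attrs = f"ID={f['id']}" if f["id"] else "."
            fh.write(f"{f['chrom']}\t{source}\t{f['type']}\t{start1}\t{end1}"
                     f"\t.\t{f['strand']}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_location_table(path) -> list[LocationCounts]:
    """TSV with columns location, latitude, longitude, temperature, n_SS, n_SN, n_NN."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyDataError(f"empty location table {path}") from None
    if df.empty:
        raise EmptyDataError(f"no rows in location table {path}")
    required = ["location", "latitude", "longitude", "temperature",
                "n_SS", "n_SN", "n_NN"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"location table missing columns: {missing}")
    return [
        LocationCounts(str(r.location), float(r.latitude), float(r.longitude),
                       float(r.temperature), int(r.n_SS), int(r.n_SN), int(r.n_NN))
        for r in df.itertuples()
    ]


def write_location_table(rows: list[LocationCounts], path) -> None:
    pd.DataFrame([{
        "location": r.location, "latitude": r.latitude, "longitude": r.longitude,
        "temperature": r.temperature, "n_SS": r.n_ss, "n_SN": r.n_sn,
        "n_NN": r.n_nn,
    } for r in rows]).to_csv(path, sep="\t", index=False)


def read_enzyme_table(path) -> list[Enzyme]:
    df = pd.read_csv(path, sep="\t")
    if "cut_offset" not in df.columns:
        df["cut_offset"] = 1
    return [Enzyme(str(r.name), str(r.site), int(r.cut_offset))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_european_locations() -> list[LocationCounts]:
    """The ten European sampling locations with karyotype counts."""
    src = resources.files("invclines.data") / "european_locations.tsv"
    with resources.as_file(src) as p:
        return read_location_table(p)


def load_default_enzymes() -> list[Enzyme]:
    """Small catalogue of common restriction enzymes (EcoRI first)."""
    src = resources.files("invclines.data") / "enzymes.tsv"
    with resources.as_file(src) as p:
        return read_enzyme_table(p)
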