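"""Localize a polymorphic inversion by sliding-window PCA and karyotype it.

A segregating inversion suppresses recombination in heterokaryotypes, so
inside the inverted interval the leading principal component of the genotype
matrix splits samples into three clusters (the two homokaryotypes flanking
the heterokaryotypes), while outside it PC1 follows ordinary population
structure. The scan scores each window for that three-cluster signature,
additionally requiring the middle cluster to be the most heterozygous (the
hallmark of heterokaryotypes), and calls the inversion as the longest run of
qualifying windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_formats import MISSING, GenotypeMatrix

#: minimum number of strongly differentiated sites (outer-cluster allele
#: frequency difference >= 0.5) for a window to count as inversion-like
MIN_SEPARATING_SITES = 3


# ---------------------------------------------------------------------------
# PCA primitives
# ---------------------------------------------------------------------------

def _centered_matrix(g: GenotypeMatrix, site_mask: np.ndarray,
                     scale: bool = False) -> np.ndarray:
    """Center dosages by 2p and mean-impute missing calls (as zeros).

    With ``scale`` the columns are divided by sqrt(2p(1-p)).
    """
    D = g.dosages[:, site_mask].astype(float)
    valid = D != MISSING
    p, _ = g.allele_frequencies(site_mask=site_mask)
    X = np.where(valid, D, 2 * p[None, :]) - 2 * p[None, :]
    if scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.sqrt(2 * p * (1 - p))
        X = np.divide(X, sd[None, :], out=np.zeros_like(X), where=sd > 0)
    return X


def _pc_scores(X: np.ndarray, samples: list[str], n_pcs: int = 2
               ) -> tuple[np.ndarray, np.ndarray]:
    """PC scores and percent variance, sign pinned to a reference sample.

    Eigenvectors are sign-ambiguous; the convention is that the sample with
    the lexicographically smallest ID has a non-negative score on each PC.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    if total == 0:
        raise ValueError("zero-variance matrix")
    k = min(n_pcs, len(s))
    scores = U[:, :k] * s[:k]
    pct = 100 * s[:k] ** 2 / total
    anchor = int(np.argmin(np.asarray(samples, dtype=object)))
    for j in range(k):
        if scores[anchor, j] < 0:
            scores[:, j] *= -1
    return scores, pct


@dataclass
class WindowPCAResult:
    """Leading-PC summary of one genomic window."""

    start: int
    end: int
    n_sites: int
    scores: np.ndarray | None       # per-sample PC1 score, None if skipped
    pct_var: float
    skipped: bool = False
    reason: str = ""


def window_pca(g: GenotypeMatrix, window: int = 50_000, step: int = 50_000,
               min_sites: int = 10, scale: bool = False
               ) -> list[WindowPCAResult]:
    """PC1 per non-overlapping (by default) window along the chromosome."""
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    pos = g.sites["pos"].to_numpy()
    out = []
    last = int(pos.max())
    for start in range(0, last + 1, step):
        end = start + window
        mask = (pos >= start) & (pos < end)
        n = int(mask.sum())
        if n < min_sites:
            out.append(WindowPCAResult(start, end, n, None, np.nan, True,
                                       "too few sites"))
            continue
        X = _centered_matrix(g, mask, scale=scale)
        try:
            scores, pct = _pc_scores(X, g.samples, n_pcs=1)
        except ValueError:
            out.append(WindowPCAResult(start, end, n, None, np.nan, True,
                                       "zero variance"))
            continue
        out.append(WindowPCAResult(start, end, n, scores[:, 0], float(pct[0])))
    return out


# ---------------------------------------------------------------------------
# trimodality scoring and region calling
# ---------------------------------------------------------------------------

def _kmeans_1d(x: np.ndarray, k: int, random_state: int, n_init: int = 10
               ) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init,
                  random_state=random_state).fit(x.reshape(-1, 1))

def _bic_kmeans(x: np.ndarray, km: KMeans) -> float:
    """BIC of a hard-assignment equal-variance Gaussian mixture."""
    n = len(x)
    labels = km.labels_
    sse = float(km.inertia_)
    sigma2 = max(sse / n, 1e-12)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    for c in range(km.n_clusters):
        nc = int((labels == c).sum())
        if nc:
            ll += nc * np.log(nc / n)
    n_params = 2 * km.n_clusters  # means + mixing weights/variance budget
    return -2 * ll + n_params * np.log(n)


def best_k(x: np.ndarray, k_max: int = 3, random_state: int = 0
           ) -> tuple[int, KMeans]:
    """Pick k in 1..k_max by minimal BIC; first-found wins on ties."""
    best = None
    for k in range(1, k_max + 1):
        if len(np.unique(x)) < k:
            break
        km = _kmeans_1d(x, k, random_state)
        bic = _bic_kmeans(x, km)
        if best is None or bic < best[0]:
            best = (bic, k, km)
    assert best is not None
    return best[1], best[2]


@dataclass
class RegionCall:
    """Called inversion interval plus the per-window diagnostic profile."""

    interval: tuple[int, int] | None
    windows: pd.DataFrame           # start, end, k, het-ordering flag, qualifies
    gap_max: int

    @property
    def empty(self) -> bool:
        return self.interval is None


def _window_qualifies(g: GenotypeMatrix, w: WindowPCAResult,
                      random_state: int, min_silhouette: float
                      ) -> tuple[int, bool]:
    """(chosen k, inversion-like?) for one window.

    Inversion-like means: BIC selects three clusters, the clusters are
    tight (silhouette >= ``min_silhouette`` - loose noise clusters on PC1
    never reach the separation a recombination-suppressed haplotype block
    produces), and the middle cluster is the most heterozygous.
    """
    k, km = best_k(w.scores, 3, random_state)
    if k != 3:
        return k, False
    if silhouette_score(w.scores.reshape(-1, 1), km.labels_) < min_silhouette:
        return k, False
    order = np.argsort(km.cluster_centers_.ravel())
    mask = (g.sites["pos"].to_numpy() >= w.start) & \
           (g.sites["pos"].to_numpy() < w.end)
    het = g.heterozygosity(site_mask=mask)
    means = [np.nanmean(het[km.labels_ == c]) for c in order]
    if not (means[1] > means[0] and means[1] > means[2]):
        return k, False
    # a true haplotype block separates the outer clusters at many sites;
    # a single high-frequency SNP driving PC1 separates them at one or two
    outer_lo = np.flatnonzero(km.labels_ == order[0])
    outer_hi = np.flatnonzero(km.labels_ == order[2])
    p_lo, _ = g.allele_frequencies(outer_lo, mask)
    p_hi, _ = g.allele_frequencies(outer_hi, mask)
    with np.errstate(invalid="ignore"):
        n_sep = int(np.nansum(np.abs(p_lo - p_hi) >= 0.5))
    return k, n_sep >= MIN_SEPARATING_SITES


def detect_inversion_region(windows: list[WindowPCAResult], g: GenotypeMatrix,
                            gap_max: int = 1, random_state: int = 0,
                            min_silhouette: float = 0.8) -> RegionCall:
    """Longest run of three-cluster, heterozygote-in-the-middle windows.

    Up to ``gap_max`` consecutive non-qualifying windows are tolerated inside
    a run; the called interval is the union of the qualifying windows'
    coordinates.
    """
    if len(windows) < 3:
        raise ValueError("need >= 3 windows")
    rows = []
    for w in windows:
        if w.skipped:
            rows.append({"start": w.start, "end": w.end, "k": 0,
                         "qualifies": False, "skipped": True})
            continue
        k, ok = _window_qualifies(g, w, random_state, min_silhouette)
        rows.append({"start": w.start, "end": w.end, "k": k,
                     "qualifies": ok, "skipped": False})
    table = pd.DataFrame(rows)
    qual = table["qualifies"].to_numpy()
    idx = np.flatnonzero(qual)
    if len(idx) == 0:
        return RegionCall(None, table, gap_max)
    # best run: maximize number of qualifying windows, allowing <= gap_max
    # non-qualifying windows between consecutive members
    best_run = [idx[0]]
    run = [idx[0]]
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a - 1 <= gap_max:
            run.append(b)
        else:
            run = [b]
        if len(run) > len(best_run):
            best_run = run
    start = int(table.loc[best_run[0], "start"])
    end = int(table.loc[best_run[-1], "end"])
    return RegionCall((start, end), table, gap_max)


# ---------------------------------------------------------------------------
# region PCA and karyotype assignment
# ---------------------------------------------------------------------------

@dataclass
class RegionPCA:
    """First two PCs of the genotype matrix restricted to an interval."""

    scores: np.ndarray              # n_samples x 2
    pct_var: np.ndarray             # length 2
    interval: tuple[int, int]
    samples: list[str]


def region_pca(g: GenotypeMatrix, interval: tuple[int, int],
               scale: bool = False) -> RegionPCA:
    mask = g.site_mask(start=interval[0], end=interval[1])
    p, n = g.allele_frequencies(site_mask=mask)
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("interval has < 2 polymorphic sites")
    X = _centered_matrix(g, mask, scale=scale)
    scores, pct = _pc_scores(X, g.samples, n_pcs=2)
    return RegionPCA(scores, pct, tuple(interval), list(g.samples))


@dataclass
class KaryotypeAssignment:
    """Per-sample inversion karyotype from the three-cluster region PCA."""

    labels: dict[str, str]
    cluster_means: dict[str, float]     # mean PC1 per karyotype label
    cluster_het: dict[str, float]       # mean heterozygosity per label
    silhouette: float
    confidence: str                     # "ok" | "low"
    failed: bool = False
    reason: str = ""
    scores: dict[str, float] = field(default_factory=dict)


def assign_karyotypes(rp: RegionPCA, g: GenotypeMatrix,
                      interval: tuple[int, int],
                      anchors: dict[str, str] | None = None,
                      random_state: int = 0) -> KaryotypeAssignment:
    """k-means (k=3) on region PC1; middle cluster is SN.

    Outer clusters are labelled from ``anchors`` (sample -> SS/NN) when
    given, otherwise the outer cluster over-represented at the
    lowest-latitude location is SS (the southern arrangement). The SN
    cluster must be the most heterozygous at region sites, else the
    assignment is flagged low-confidence.
    """
    if len(rp.samples) < 3:
        return KaryotypeAssignment({}, {}, {}, np.nan, "low", True,
                                   "fewer than 3 samples")
    x = rp.scores[:, 0]
    if len(np.unique(x)) < 3:
        return KaryotypeAssignment({}, {}, {}, np.nan, "low", True,
                                   "fewer than 3 distinct PC1 values")
    km = KMeans(n_clusters=3, n_init=20, random_state=random_state) \
        .fit(x.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())  # low, mid, high
    cluster_of = {int(c): rank for rank, c in enumerate(order)}
    ranks = np.array([cluster_of[int(c)] for c in km.labels_])

    # decide which outer rank (0 or 2) is SS
    ss_rank = None
    if anchors:
        votes = {0: 0, 2: 0}
        for s, lab in anchors.items():
            if s in rp.samples and lab in ("SS", "NN"):
                r = ranks[rp.samples.index(s)]
                if r in (0, 2):
                    votes[r] += 1 if lab == "SS" else -1
        if votes[0] != votes[2]:
            ss_rank = 0 if votes[0] > votes[2] else 2
    if ss_rank is None and g.sample_meta is not None and \
            "latitude" in g.sample_meta.columns:
        lat = g.sample_meta.loc[rp.samples, "latitude"].to_numpy(dtype=float)
        south = lat == np.nanmin(lat)
        f0 = (ranks[south] == 0).mean()
        f2 = (ranks[south] == 2).mean()
        ss_rank = 0 if f0 >= f2 else 2
    if ss_rank is None:
        ss_rank = 0  # deterministic fallback
    rank_label = {ss_rank: "SS", 1: "SN", (2 if ss_rank == 0 else 0): "NN"}

    labels = {s: rank_label[r] for s, r in zip(rp.samples, ranks)}
    mask = g.site_mask(start=interval[0], end=interval[1])
    het = g.heterozygosity(site_mask=mask)
    cl_means = {rank_label[r]: float(x[ranks == r].mean()) for r in range(3)}
    cl_het = {rank_label[r]: float(np.nanmean(het[ranks == r]))
              for r in range(3)}
    sil = float(silhouette_score(x.reshape(-1, 1), ranks))
    conf = "ok" if cl_het["SN"] >= max(cl_het["SS"], cl_het["NN"]) else "low"
    return KaryotypeAssignment(labels, cl_means, cl_het, sil, conf,
                               scores=dict(zip(rp.samples, x.tolist())))
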