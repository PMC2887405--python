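"""Segregating sites and the pi / Watterson-theta diversity estimators.

All statistics are SNP-based and computed on the gap-free core alignment:
a core column is segregating iff at least two distinct bases occur there.
Indel events never contribute to S, pi or theta; they are catalogued
separately for the functional-region mutation tables.

Per-locus values follow the classical estimators: theta_W = S / a1(n) with
a1 the (n-1)-th partial harmonic sum, and pi (k-hat) the unweighted mean
count of differing core sites over all n(n-1)/2 unordered sequence pairs
(no n/(n-1) correction).  Per-site values divide by the core length L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import AlignedLocus, CoreAlignment, IndelEvent, LocusAnnotation


def harmonic(n: int, power: int = 1) -> float:
    """Partial harmonic sum a = sum_{i=1}^{n-1} 1/i**power."""
    if n < 2:
        raise ValueError("harmonic sums need n >= 2")
    i = np.arange(1, n, dtype=float)
    return float((1.0 / i**power).sum())


@dataclass(frozen=True)
class SegregatingSite:
    core_position: int
    alignment_position: int
    alleles: dict[str, int]


@dataclass(frozen=True)
class SiteCatalog:
    locus_id: str
    n: int
    sites: tuple[SegregatingSite, ...]
    indels: tuple[IndelEvent, ...]

    @property
    def S(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class DiversityStats:
    """Per-locus diversity summary for one accession group.

    ``pi_locus`` is k-hat (mean pairwise differences per locus); the
    per-site fields divide by the core length L.  When L = 0 the statistics
    are undefined and stored as NaN with ``defined`` False.
    """

    n: int
    L: int
    S: int
    theta_w_locus: float
    pi_locus: float
    theta_w_site: float
    pi_site: float
    snp_per_kb: float

    @property
    def defined(self) -> bool:
        return self.L > 0


@dataclass(frozen=True)
class AggregateDiversity:
    group: str
    values: tuple[float, ...]
    mean: float
    sem: float
    n_loci: int


def find_segregating_sites(core: CoreAlignment) -> SiteCatalog:
    """Catalogue segregating core columns plus the core's indel events."""
    if core.n < 2:
        raise ValueError(f"{core.locus_id}: need >=2 sequences")
    sites = []
    mat = core.matrix
    if core.L:
        codes = _encode(mat)
        counts = _allele_counts(codes)
        seg = (counts > 0).sum(axis=1) >= 2
        for j in np.flatnonzero(seg):
            alleles = {
                b: int(c) for b, c in zip("ACGT", counts[j]) if c > 0
            }
            sites.append(
                SegregatingSite(
                    core_position=int(j),
                    alignment_position=int(core.kept_columns[j]),
                    alleles=alleles,
                )
            )
    return SiteCatalog(core.locus_id, core.n, tuple(sites), core.indel_events)


def watterson_theta(S: int, n: int) -> float:
    """Per-locus Watterson estimator S / a1(n)."""
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / harmonic(n)


def pairwise_pi(core: CoreAlignment) -> tuple[float, float]:
    """(k-hat, k-hat / L): mean pairwise differences per locus and per site.

    Computed from per-column allele counts: the number of differing pairs at
    a column with counts c_a is C(n,2) - sum_a C(c_a,2).
    """
    if core.n < 2:
        raise ValueError(f"{core.locus_id}: need >=2 sequences")
    if core.empty:
        return math.nan, math.nan
    counts = _allele_counts(_encode(core.matrix))
    n = core.n
    pairs = n * (n - 1) / 2.0
    diff_pairs = pairs - (counts * (counts - 1) / 2.0).sum(axis=1)
    k_hat = float(diff_pairs.sum() / pairs)
    return k_hat, k_hat / core.L


def diversity_stats(core: CoreAlignment) -> DiversityStats:
    catalog = find_segregating_sites(core)
    S = catalog.S
    if core.empty:
        return DiversityStats(core.n, 0, 0, math.nan, math.nan, math.nan,
                              math.nan, math.nan)
    pi_locus, pi_site = pairwise_pi(core)
    theta = watterson_theta(S, core.n)
    return DiversityStats(
        n=core.n,
        L=core.L,
        S=S,
        theta_w_locus=theta,
        pi_locus=pi_locus,
        theta_w_site=theta / core.L,
        pi_site=pi_site,
        snp_per_kb=1000.0 * S / core.L,
    )


def region_diversity(
    core: CoreAlignment, annotation: LocusAnnotation
) -> dict[str, DiversityStats]:
    """Diversity per annotated region, on the region's surviving core columns.

    Regions entirely lost from the core yield undefined (NaN) statistics.
    Keys are region keys (label, or 'label:name' for named phases).
    """
    out: dict[str, DiversityStats] = {}
    for region in annotation.regions:
        cols = core.map_region(region.start, region.end)
        out[region.key] = diversity_stats(core.restrict(cols))
    return out


def aggregate(group: str, values: Iterable[float]) -> AggregateDiversity:
    """Mean and SEM of a per-locus statistic across loci.

    NaN (undefined) entries are dropped; a single-locus group has SEM 0 so
    report tables stay total.
    """
    vals = tuple(float(v) for v in values if not math.isnan(float(v)))
    if not vals:
        raise ValueError(f"aggregate group {group!r} is empty")
    arr = np.asarray(vals)
    sem = 0.0 if arr.size == 1 else float(arr.std(ddof=1) / math.sqrt(arr.size))
    return AggregateDiversity(group, vals, float(arr.mean()), sem, arr.size)


# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(mat: np.ndarray) -> np.ndarray:
    codes = np.zeros(mat.shape, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        codes[mat == b] = c
    return codes


def _allele_counts(codes: np.ndarray) -> np.ndarray:
    """(L, 4) allele counts per column from an (n, L) code matrix."""
    n, L = codes.shape
    counts = np.zeros((L, 4), dtype=np.int64)
    for c in range(4):
        counts[:, c] = (codes == c).sum(axis=0)
    return counts
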