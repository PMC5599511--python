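"""Partition similarity metrics and boundary feature enrichment.

Variation of Information (VI) between two partitions A, B of the same
bin set, in nats:

    VI(A;B) = - sum_ij r_ij [ log(r_ij / p_i) + log(r_ij / q_j) ]

with p_i = |A_i|/n, q_j = |B_j|/n, r_ij = |A_i ∩ B_j|/n; zero-mass cells
contribute 0.  VI is 0 iff the partitions are identical and is bounded
by log(n).  Since VI needs disjoint covering subsets it cannot compare
hierarchies directly; domain sets are converted level by level (gaps
become their own subsets), and hierarchies are otherwise compared with
the best-match Jaccard index.

Boundary enrichment follows the randomization scheme of placing, many
times, the same number of regions with the same sizes uniformly on the
chromosome and recomputing the fraction of region boundaries that
overlap at least one feature; the p-value uses the add-one estimator
(1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import Domain, DomainSet, GenomicInterval
from .simulate import partition_from_intervals

__all__ = [
    "Partition",
    "EnrichmentResult",
    "variation_of_information",
    "jaccard_interval",
    "jaccard_set_similarity",
    "domainset_to_partition",
    "features_per_boundary",
    "boundary_overlap_fraction",
    "permutation_enrichment",
]

Partition = list[set[int]]


@dataclass
class EnrichmentResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int


def _check_partition(p: Partition) -> set[int]:
    ground: set[int] = set()
    for s in p:
        if not s:
            raise ValueError("partition contains an empty subset")
        if ground & s:
            raise ValueError("partition subsets are not disjoint")
        ground |= s
    return ground


def variation_of_information(a: Partition, b: Partition) -> float:
    """VI between two partitions of the same ground set, in nats."""
    ga, gb = _check_partition(a), _check_partition(b)
    if ga != gb:
        raise ValueError("partitions cover different ground sets")
    n = len(ga)
    vi = 0.0
    for ai in a:
        pi = len(ai) / n
        for bj in b:
            inter = len(ai & bj)
            if inter == 0:
                continue
            rij = inter / n
            qj = len(bj) / n
            vi -= rij * (np.log(rij / pi) + np.log(rij / qj))
    return max(0.0, float(vi))


def jaccard_interval(a: Domain | tuple[int, int], b: Domain | tuple[int, int]) -> float:
    """Jaccard index of two half-open bin intervals."""
    sa, ea = (a.start_bin, a.end_bin) if isinstance(a, Domain) else a
    sb, eb = (b.start_bin, b.end_bin) if isinstance(b, Domain) else b
    inter = max(0, min(ea, eb) - max(sa, sb))
    union = (ea - sa) + (eb - sb) - inter
    return inter / union if union else 0.0


def jaccard_set_similarity(a: DomainSet | list, b: DomainSet | list) -> float:
    """Symmetrized best-match Jaccard between two domain sets.

    Each domain of A is matched to its best Jaccard partner in B and
    vice versa; the two mean best-match scores are averaged.  1 iff the
    two sets are identical as interval sets.
    """
    da = list(a.domains) if isinstance(a, DomainSet) else list(a)
    db = list(b.domains) if isinstance(b, DomainSet) else list(b)
    if not da or not db:
        raise ValueError("jaccard_set_similarity needs nonempty domain sets")
    ab = np.mean([max(jaccard_interval(x, y) for y in db) for x in da])
    ba = np.mean([max(jaccard_interval(y, x) for x in da) for y in db])
    return float((ab + ba) / 2.0)


def domainset_to_partition(ds: DomainSet, n_bins: int, level: int = 0) -> Partition:
    """Convert one hierarchy level to a partition; uncovered stretches
    (gaps) become their own subsets."""
    ivs = [(d.start_bin, d.end_bin) for d in ds.at_level(level)]
    return partition_from_intervals(ivs, n_bins)


# ---------------------------------------------------------------------------
# Boundary features
# ---------------------------------------------------------------------------

def _boundary_bins(domains) -> list[int]:
    """The single bin at each domain edge (start bin and last bin),
    deduplicated and ordered."""
    bins = set()
    for d in domains:
        bins.add(d.start_bin)
        bins.add(d.end_bin - 1)
    return sorted(bins)


def _boundary_windows(ds: DomainSet, flank_bp: int, domains=None):
    res = ds.resolution_bp
    doms = ds.domains if domains is None else domains
    for b in _boundary_bins(doms):
        yield (max(0, b * res - flank_bp), (b + 1) * res + flank_bp)


def _count_overlaps(window: tuple[int, int], features: list[GenomicInterval]) -> int:
    w0, w1 = window
    return sum(1 for f in features if f.start_bp < w1 and f.end_bp > w0)


def features_per_boundary(
    ds: DomainSet,
    features: list[GenomicInterval],
    flank_bp: int = 25_000,
) -> float:
    """Mean number of features overlapping each boundary window
    (boundary bin's genomic span extended by ``flank_bp`` on both
    sides; half-open overlap)."""
    windows = list(_boundary_windows(ds, flank_bp))
    if not windows:
        raise ValueError("domain set has no boundaries")
    return float(np.mean([_count_overlaps(w, features) for w in windows]))


def boundary_overlap_fraction(
    ds: DomainSet,
    features: list[GenomicInterval],
    flank_bp: int = 0,
    domains=None,
) -> float:
    """Fraction of boundary windows overlapping at least one feature."""
    windows = list(_boundary_windows(ds, flank_bp, domains))
    if not windows:
        raise ValueError("domain set has no boundaries")
    return float(np.mean([_count_overlaps(w, features) > 0 for w in windows]))


def _place_random_regions(rng, sizes_bins, n_bins, max_tries=1000):
    """Uniform non-overlapping placement of regions with given bin sizes."""
    for _ in range(max_tries):
        placed = []
        ok = True
        for size in sorted(sizes_bins, reverse=True):
            spots = [
                s for s in rng.integers(0, n_bins - size + 1, 50)
                if all(s + size <= ps or s >= pe for ps, pe in placed)
            ]
            if not spots:
                ok = False
                break
            s = int(spots[0])
            placed.append((s, s + size))
        if ok:
            return [Domain(s, e) for s, e in sorted(placed)]
    raise ValueError("could not place non-overlapping random regions")


def permutation_enrichment(
    ds: DomainSet,
    features: list[GenomicInterval],
    chrom_len_bp: int,
    n_perm: int = 10_000,
    seed: int = 0,
    flank_bp: int = 0,
) -> EnrichmentResult:
    """Random-region permutation test for boundary feature enrichment.

    The observed statistic is the fraction of domain boundaries whose
    (flanked) window overlaps at least one feature.  Each permutation
    re-places the same number of regions with the same sizes uniformly
    and without overlap on the chromosome and recomputes the fraction.
    """
    n_bins = chrom_len_bp // ds.resolution_bp
    span = max((d.end_bin for d in ds.domains), default=0)
    if n_bins < span:
        raise ValueError("chrom_len_bp shorter than the domain set span")
    observed = boundary_overlap_fraction(ds, features, flank_bp)
    sizes = [d.size_bins for d in ds.domains]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        regions = _place_random_regions(rng, sizes, n_bins)
        null[k] = boundary_overlap_fraction(ds, features, flank_bp, domains=regions)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return EnrichmentResult(observed=observed, null_distribution=null,
                            p_value=float(p), n_perm=n_perm)
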