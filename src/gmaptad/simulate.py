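"""Truth-labeled Hi-C contact-matrix simulator.

Upper-triangle counts are drawn independently with a 1/distance decay:
background entries with mean ``u / |i-j|``, entries inside an embedded
TAD with mean ``t*u / |i-j|`` and entries inside a nested subTAD with
mean ``s*t*u / |i-j|`` (``max(1, |i-j|)`` on the diagonal so it matches
the distance-1 intensity).  Counts are Poisson by default; the
negative-binomial mode keeps the same means and sets the dispersion so
the variance is ``nb_var_factor`` times the mean (size parameter
``r = mu / (nb_var_factor - 1)``).

Defaults follow the simulation study conditions: 1000x1000 bins,
u = 200, t = s = 2, ten TADs with sizes 40-175 bins placed without
overlap along the diagonal, and two TAD-free gap regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMatrix, Domain, DomainSet

__all__ = ["SimConfig", "SimTruth", "simulate_hic", "truth_partition"]


@dataclass
class SimConfig:
    n_bins: int = 1000
    u: float = 200.0           # background intensity at distance 1
    t: float = 2.0             # TAD / background signal ratio
    s: float = 2.0             # subTAD / TAD signal ratio
    n_tads: int = 10
    tad_size_range: tuple[int, int] = (40, 175)
    n_gaps: int = 2
    distribution: str = "poisson"   # or "negbinom"
    nb_var_factor: float = 1.25
    with_subtads: bool = False
    resolution_bp: int = 40_000
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("u must be > 0")
        if self.t < 1 or self.s < 1:
            raise ValueError("signal ratios t, s must be >= 1")
        if self.nb_var_factor <= 1:
            raise ValueError("nb_var_factor must be > 1")
        if self.distribution not in ("poisson", "negbinom"):
            raise ValueError("distribution must be 'poisson' or 'negbinom'")
        lo, hi = self.tad_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid tad_size_range")
        if self.n_tads * lo > self.n_bins:
            raise ValueError("infeasible packing: minimal TAD sizes exceed n_bins")


@dataclass
class SimTruth:
    cm: ContactMatrix
    tads: list[Domain] = field(default_factory=list)
    subtads: list[Domain] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def domain_set(self) -> DomainSet:
        return DomainSet(self.tads + self.subtads, chrom=self.cm.chrom,
                         resolution_bp=self.cm.resolution_bp,
                         n_bins=self.cm.n_bins)


def _draw_sizes(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """TAD and gap-region sizes, uniform on the stated range, redrawn as a
    vector until everything fits in the chromosome.  Gap regions are
    embedded like TADs, so their sizes follow the same distribution."""
    lo, hi = cfg.tad_size_range
    for _ in range(10_000):
        sizes = rng.integers(lo, hi + 1, cfg.n_tads + cfg.n_gaps)
        if sizes.sum() <= cfg.n_bins:
            return sizes[:cfg.n_tads], sizes[cfg.n_tads:]
    raise ValueError("infeasible packing: could not draw TAD sizes that fit")


def _place_tads(rng: np.random.Generator, cfg: SimConfig):
    """Tile TADs adjacently along the diagonal and insert exactly
    ``n_gaps`` TAD-free stretches at random interior slots; the free bins
    left over by the size draw are split randomly over the gap regions."""
    sizes, gap_sizes = _draw_sizes(rng, cfg)
    free = cfg.n_bins - int(sizes.sum()) - int(gap_sizes.sum())
    n_slots = cfg.n_tads + 1
    offsets = np.zeros(n_slots, dtype=int)
    placed = 0
    if gap_sizes.size:
        interior = np.arange(1, n_slots - 1)
        k = min(gap_sizes.size, interior.size)
        slots = rng.choice(interior, size=k, replace=False)
        for slot, width in zip(slots, gap_sizes[:k]):
            offsets[slot] = int(width)
            placed += int(width)
    # leftover background (and any gap that found no interior slot) goes
    # to the chromosome ends: TAD start bins are random, so the ends
    # carry plain background
    free += int(gap_sizes.sum()) - placed
    lead = int(rng.integers(0, free + 1)) if free > 0 else 0
    offsets[0] += lead
    offsets[-1] += free - lead
    tads = []
    pos = 0
    for k_, size in enumerate(sizes):
        pos += int(offsets[k_])
        tads.append(Domain(pos, pos + int(size), level=0))
        pos += int(size)
    gaps = [(g0, g1) for (g0, g1) in _complement(tads, cfg.n_bins)]
    return tads, gaps


def _complement(tads, n_bins):
    pos = 0
    for t in tads:
        if t.start_bin > pos:
            yield (pos, t.start_bin)
        pos = t.end_bin
    if pos < n_bins:
        yield (pos, n_bins)


def _place_subtads(rng: np.random.Generator, tads, min_size: int = 5):
    """Two nested subTADs per TAD large enough to host them.

    The TAD is split at a random interior point and each side hosts one
    subTAD covering 50-90% of its side (subTADs are substantial blocks,
    a few hundred kb, not slivers)."""
    subs = []
    for t in tads:
        size = t.size_bins
        if size < 4 * min_size:
            continue
        split = int(rng.integers(t.start_bin + 2 * min_size,
                                 t.end_bin - 2 * min_size + 1))
        for lo, hi in ((t.start_bin, split), (split, t.end_bin)):
            span = hi - lo
            ssize = max(min_size, int(span * rng.uniform(0.5, 0.9)))
            start = int(rng.integers(lo, hi - ssize + 1))
            subs.append(Domain(start, start + ssize, level=1, parent=t))
    return subs


def simulate_hic(cfg: SimConfig) -> SimTruth:
    """Generate a symmetric integer contact matrix with known truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    tads, gaps = _place_tads(rng, cfg)
    subtads = _place_subtads(rng, tads) if cfg.with_subtads else []

    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dist = np.maximum(1, np.abs(i - j))
    lam = cfg.u / dist
    for t in tads:
        sl = slice(t.start_bin, t.end_bin)
        lam[sl, sl] = cfg.t * cfg.u / dist[sl, sl]
    for st in subtads:
        sl = slice(st.start_bin, st.end_bin)
        lam[sl, sl] = cfg.s * cfg.t * cfg.u / dist[sl, sl]

    if cfg.distribution == "poisson":
        draws = rng.poisson(lam)
    else:
        r = lam / (cfg.nb_var_factor - 1.0)  # var = mu + mu^2/r = factor*mu
        p = r / (r + lam)
        draws = rng.negative_binomial(r, p)
    upper = np.triu(draws, k=1)
    values = upper + upper.T + np.diag(np.diag(draws))
    cm = ContactMatrix(values.astype(float), cfg.resolution_bp, chrom=cfg.chrom)
    return SimTruth(cm=cm, tads=tads, subtads=subtads, gaps=gaps)


def truth_partition(st: SimTruth, level: int = 0) -> list[set[int]]:
    """Disjoint bin subsets: each domain at ``level`` plus each maximal
    uncovered stretch as its own subset (feeds the VI metric)."""
    if level not in (0, 1):
        raise ValueError("level must be 0 or 1")
    doms = st.tads if level == 0 else st.subtads
    return partition_from_intervals(
        [(d.start_bin, d.end_bin) for d in doms], st.cm.n_bins)


def partition_from_intervals(intervals: list[tuple[int, int]], n_bins: int) -> list[set[int]]:
    """Partition of range(n_bins): one subset per interval, one per maximal
    uncovered stretch."""
    ordered = sorted(intervals)
    subsets = []
    pos = 0
    for s, e in ordered:
        if s < pos:
            raise ValueError("intervals overlap")
        if s > pos:
            subsets.append(set(range(pos, s)))
        subsets.append(set(range(s, e)))
        pos = e
    if pos < n_bins:
        subsets.append(set(range(pos, n_bins)))
    return [s for s in subsets if s]
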