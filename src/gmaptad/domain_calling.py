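"""TAD assembly from oriented peaks, parameter tuning, and subTAD recursion.

A TAD opens at a downstream-biased peak, extends through consecutive
downstream-biased peaks, and closes at the next upstream-biased or
unbiased peak; an unbiased peak is shared by two consecutive TADs (it
closes one and opens the next).  Regions not covered by any TAD are gaps.

The four free parameters (window size ``d``, minimal peak separation
``d_p``, peak threshold ``t1``, directionality threshold ``t2``) are
tuned by maximizing the separation between the proportion of
intra-domain contacts inside called TADs and in the background (bin
pairs within the distance cap D that fall outside all TADs), measured as
a two-proportion z statistic.

SubTADs are called by re-applying the whole procedure to the submatrix
of each called TAD (fresh mixture fit, fresh statistics, fresh tuning
with the TAD itself as background), recursing until no peak is
significant, candidate domains fall below the minimal domain size
(200 kb by default), or the level cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .hic_io import ContactMatrix, Domain, DomainSet
from .mixture import (DEFAULT_MAX_DIST_BP, StateMatrix, eligible_values,
                      fit_gmm, max_dist_bins, state_matrix)
from .boundary_stats import compute_boundary_track

__all__ = [
    "GmapParams",
    "ParamGrid",
    "TuningResult",
    "assemble_domains",
    "gap_intervals",
    "tuning_objective",
    "tune_parameters",
    "call_domains",
    "call_hierarchy",
]

DEFAULT_MIN_DOMAIN_BP = 200_000


@dataclass(frozen=True)
class GmapParams:
    """The four tunable parameters plus global size/distance settings.

    ``min_prominence`` is part of the local-peak definition (see
    :func:`gmaptad.boundary_stats.find_peaks`); ``prune_z`` is the
    per-domain significance threshold: a called domain whose own
    intra-domain proportion is not above background by more than this
    two-proportion z value is reclassified as gap.
    """

    d: int = 12
    d_p: int = 5
    t1: float = 10.0
    t2: float = 4.0
    max_dist_bp: int = DEFAULT_MAX_DIST_BP
    min_domain_bp: int = DEFAULT_MIN_DOMAIN_BP
    max_level: int = 2
    min_prominence: float | None = 5.0
    prune_z: float | None = 2.0

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.d_p < 1:
            raise ValueError("d_p must be >= 1")
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.t2 < 0:
            raise ValueError("t2 must be >= 0")


@dataclass(frozen=True)
class ParamGrid:
    """Search ranges for the four tunable parameters.

    The default ``d`` values span 0.4-0.7 Mb windows at 40 kb resolution,
    the TAD scale reported across mammalian Hi-C studies.  With
    ``t1=None`` (the default) the peak threshold is coupled to the window
    size as ``t1 = d``: the Z statistic at a saturated block boundary is
    ``2d``, so this is a half-maximum rule that keeps the searched calls
    away from noise-driven over-segmentation.
    """

    d: tuple[int, ...] = (10, 12, 15, 18)
    d_p: tuple[int, ...] = (5, 7)
    t1: tuple[float, ...] | None = None
    t2: tuple[float, ...] = (3.0, 4.0, 5.0)

    def points(self):
        for d in self.d:
            t1s = (float(d),) if self.t1 is None else self.t1
            for t1, d_p, t2 in product(t1s, self.d_p, self.t2):
                yield d, d_p, t1, t2

    def __len__(self):
        n_t1 = 1 if self.t1 is None else len(self.t1)
        return len(self.d) * len(self.d_p) * n_t1 * len(self.t2)


@dataclass
class TuningResult:
    best: GmapParams
    table: list[tuple[GmapParams, float, int, int]] = field(default_factory=list)


#: Default grid for the subTAD recursion.  Within a TAD the intra/inter
#: contrast is weaker (the state matrix is largely saturated near the
#: diagonal), so the window must reach past the in-TAD contact band and
#: the peak threshold sits much lower than at the chromosome level.
SUBTAD_GRID = ParamGrid(d=(15, 20, 25, 30), d_p=(5, 7),
                        t1=(2.0, 3.0, 5.0), t2=(2.0, 3.0))


# ---------------------------------------------------------------------------
# Step 3: assembly
# ---------------------------------------------------------------------------

def assemble_domains(
    peaks: list[int],
    orientations: list[str],
    n_bins: int,
    chrom: str = "chr1",
    resolution_bp: int = 40_000,
) -> tuple[DomainSet, list[tuple[int, int]]]:
    """Assemble level-0 TADs and gaps from oriented peaks.

    Returns the TADs as a DomainSet and the gaps as half-open bin
    intervals; every bin belongs to exactly one TAD or gap.  A shared
    unbiased junction bin is the exclusive end of the left TAD and the
    inclusive start of the right one.  With zero peaks the whole
    chromosome is one gap.
    """
    if len(peaks) != len(orientations):
        raise ValueError("peaks and orientations must align")
    tads: list[Domain] = []
    open_start: int | None = None
    in_gap = False  # an upstream-biased peak explicitly opened a gap
    for p, o in zip(peaks, orientations):
        if o == "down":
            if open_start is None:
                open_start = p
            # consecutive downstream-biased peaks extend the open TAD
            in_gap = False
        elif o == "up":
            if open_start is not None and p > open_start:
                tads.append(Domain(open_start, p, level=0))
            open_start = None
            in_gap = True  # gap extends to the next downstream-biased peak
        else:  # unbiased: shared junction of two consecutive TADs
            if open_start is not None and p > open_start:
                tads.append(Domain(open_start, p, level=0))
                open_start = p
            elif not in_gap:
                # neutral context (e.g. first peak): treat as a TAD start,
                # but never inside an explicitly opened gap
                open_start = p
    # a TAD opened by the last peak has no closing boundary: the region
    # after the last peak is a gap, so it is dropped
    ds = DomainSet(tads, chrom=chrom, resolution_bp=resolution_bp, n_bins=n_bins)
    return ds, gap_intervals(ds, n_bins)


def gap_intervals(ds: DomainSet, n_bins: int) -> list[tuple[int, int]]:
    """Maximal bin stretches not covered by any level-0 domain."""
    gaps = []
    pos = 0
    for d in ds.at_level(0):
        if d.start_bin > pos:
            gaps.append((pos, d.start_bin))
        pos = max(pos, d.end_bin)
    if pos < n_bins:
        gaps.append((pos, n_bins))
    return gaps


# ---------------------------------------------------------------------------
# Tuning objective
# ---------------------------------------------------------------------------

def _band_integrals(h: np.ndarray, max_dist_bins: int):
    """Summed-area tables of h and of the pair-count mask over the band
    1 <= |i-j| <= max_dist_bins."""
    n = h.shape[0]
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    band = (dist >= 1) & (dist <= max_dist_bins)
    a = np.where(band, h, 0.0)
    c = band.astype(float)
    sa = np.zeros((n + 1, n + 1))
    sc = np.zeros((n + 1, n + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=sa[1:, 1:])
    np.cumsum(np.cumsum(c, axis=0), axis=1, out=sc[1:, 1:])
    return sa, sc


def _square_sum(s: np.ndarray, lo: int, hi: int) -> float:
    """Sum over the [lo, hi) x [lo, hi) box."""
    return s[hi, hi] - s[lo, hi] - s[hi, lo] + s[lo, lo]


def tuning_objective(
    sm: StateMatrix | np.ndarray,
    ds: DomainSet,
    max_dist_bins: int,
    mode: str = "corrected",
    _integrals=None,
) -> float:
    """Two-proportion separation of intra-TAD vs background contact state.

    Counted over upper-triangle pairs with 1 <= j - i <= max_dist_bins;
    background pairs are those in the band but in no level-0 TAD.  The
    default ``corrected`` mode is the classical pooled two-proportion z
    statistic; ``literal`` uses the printed variance factor
    (1/n_TAD - 1/n_bg) and signed pooled p, guarded to 0 when the
    variance term is nonpositive.  An empty TAD set returns -inf.
    """
    h = sm.h if isinstance(sm, StateMatrix) else np.asarray(sm)
    tads = ds.at_level(0)
    if not tads:
        return float("-inf")
    sa, sc = _integrals if _integrals is not None else _band_integrals(h, max_dist_bins)
    tad_sum = sum(_square_sum(sa, t.start_bin, t.end_bin) for t in tads) / 2.0
    tad_cnt = sum(_square_sum(sc, t.start_bin, t.end_bin) for t in tads) / 2.0
    n = h.shape[0]
    tot_sum = _square_sum(sa, 0, n) / 2.0
    tot_cnt = _square_sum(sc, 0, n) / 2.0
    bg_sum = tot_sum - tad_sum
    bg_cnt = tot_cnt - tad_cnt
    if tad_cnt <= 0 or bg_cnt <= 0:
        return float("-inf")
    p_tad = tad_sum / tad_cnt
    p_bg = bg_sum / bg_cnt
    if mode == "corrected":
        p = (tad_sum + bg_sum) / (tad_cnt + bg_cnt)
        var = p * (1 - p) * (1 / tad_cnt + 1 / bg_cnt)
    elif mode == "literal":
        p = (p_tad * tad_cnt - p_bg * bg_cnt) / (tad_cnt + bg_cnt)
        var = p * (1 - p) * (1 / tad_cnt - 1 / bg_cnt)
    else:
        raise ValueError(f"unknown objective mode {mode!r}")
    if var <= 0:
        return 0.0
    return float((p_tad - p_bg) / np.sqrt(var))


def prune_weak_domains(
    sm: StateMatrix | np.ndarray,
    domains: list[Domain],
    n_bins: int,
    max_dist_bins: int,
    z_min: float = 2.0,
    _integrals=None,
) -> list[Domain]:
    """Drop called domains indistinguishable from background.

    Applies the tuning statistic per domain: a domain is kept only when
    its own intra-domain contact proportion exceeds the background
    proportion by more than ``z_min`` on the two-proportion z scale.
    This reclassifies as gaps the blocks that the peak orientation could
    not resolve (both edges read unbiased inside a contact desert).
    """
    h = sm.h if isinstance(sm, StateMatrix) else np.asarray(sm)
    sa, sc = _integrals if _integrals is not None else _band_integrals(h, max_dist_bins)
    tot_s = _square_sum(sa, 0, n_bins) / 2.0
    tot_c = _square_sum(sc, 0, n_bins) / 2.0
    kept = []
    for t in domains:
        ts = _square_sum(sa, t.start_bin, t.end_bin) / 2.0
        tc = _square_sum(sc, t.start_bin, t.end_bin) / 2.0
        bs, bc = tot_s - ts, tot_c - tc
        if tc < 1 or bc < 1:
            continue
        p1, p2 = ts / tc, bs / bc
        p = (ts + bs) / (tc + bc)
        var = p * (1 - p) * (1 / tc + 1 / bc)
        z = (p1 - p2) / np.sqrt(var) if var > 0 else 0.0
        if z > z_min:
            kept.append(t)
    return kept


def _postprocess(tads, params: GmapParams, resolution_bp: int, n_bins: int,
                 sm: StateMatrix, integrals):
    """Minimal-size filter + background-likeness pruning of level-0 calls."""
    min_bins = _min_domain_bins(params.min_domain_bp, resolution_bp)
    tads = [t for t in tads if t.size_bins >= min_bins]
    if params.prune_z is not None:
        maxd = max_dist_bins(resolution_bp, params.max_dist_bp)
        tads = prune_weak_domains(sm, tads, n_bins, maxd, params.prune_z,
                                  _integrals=integrals)
    return tads


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def tune_parameters(
    cm: ContactMatrix,
    grid: ParamGrid | None = None,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    min_domain_bp: int = DEFAULT_MIN_DOMAIN_BP,
    log_transform: bool = True,
    objective: str = "corrected",
    sm: StateMatrix | None = None,
    min_prominence: float | None = 5.0,
    prune_z: float | None = 2.0,
) -> TuningResult:
    """Grid-search (d, d_p, t1, t2) maximizing the tuning objective.

    The mixture is fit once per matrix; only the window statistics and
    peak calling are recomputed per grid point.  The objective is
    evaluated on the post-processed call (minimal-size filter and
    background pruning applied).  Ties are broken toward smaller ``d``,
    then smaller ``t1``.  Raises if no grid point calls any TAD.
    """
    grid = grid or ParamGrid()
    maxd = max_dist_bins(cm.resolution_bp, max_dist_bp)
    if sm is None:
        gmm = fit_gmm(eligible_values(cm, maxd, log_transform),
                      log_transform=log_transform)
        sm = state_matrix(cm, gmm, max_dist_bins=maxd)
    integrals = _band_integrals(sm.h, maxd)

    table: list[tuple[GmapParams, float, int, int]] = []
    best: GmapParams | None = None
    best_key: tuple[float, int, float] | None = None
    from .boundary_stats import (classify_orientation, d_statistic,
                                 find_peaks, proportion_tracks, z_statistic)
    for d in grid.d:
        if d < 2 or d >= cm.n_bins:
            continue
        pw, pb, pu, pd_ = proportion_tracks(sm.h, d)
        z = z_statistic(pw, pb, d)
        dvec = d_statistic(pu, pd_, d)
        for t1 in ((float(d),) if grid.t1 is None else grid.t1):
            for d_p in grid.d_p:
                peaks = find_peaks(z, t1, d_p, min_prominence)
                for t2 in grid.t2:
                    gp = GmapParams(d=d, d_p=d_p, t1=t1, t2=t2,
                                    max_dist_bp=max_dist_bp,
                                    min_domain_bp=min_domain_bp,
                                    min_prominence=min_prominence,
                                    prune_z=prune_z)
                    orient = classify_orientation(dvec, peaks, t2)
                    ds, _ = assemble_domains(peaks, orient, cm.n_bins,
                                             cm.chrom, cm.resolution_bp)
                    tads = _postprocess(ds.at_level(0), gp, cm.resolution_bp,
                                        cm.n_bins, sm, integrals)
                    ds = DomainSet(tads, chrom=cm.chrom,
                                   resolution_bp=cm.resolution_bp,
                                   n_bins=cm.n_bins)
                    obj = tuning_objective(sm, ds, maxd, mode=objective,
                                           _integrals=integrals)
                    n_tad = sum(
                        _square_sum(integrals[1], t.start_bin, t.end_bin)
                        for t in ds.at_level(0)) / 2.0
                    n_tot = _square_sum(integrals[1], 0, cm.n_bins) / 2.0
                    table.append((gp, obj, int(n_tad), int(n_tot - n_tad)))
                    if np.isfinite(obj):
                        key = (-obj, d, t1)
                        if best_key is None or key < best_key:
                            best, best_key = gp, key
    if best is None:
        raise ValueError("no domains callable at any grid point")
    return TuningResult(best=best, table=table)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_domains(
    cm: ContactMatrix,
    params: GmapParams | None = None,
    log_transform: bool = True,
    sm: StateMatrix | None = None,
) -> tuple[DomainSet, list[tuple[int, int]]]:
    """Single-level TAD call with fixed parameters.

    Returns the called TADs (after the minimal-size filter and
    background pruning) together with the gap intervals (the complement
    of the TADs).
    """
    params = params or GmapParams()
    maxd = max_dist_bins(cm.resolution_bp, params.max_dist_bp)
    if sm is None:
        gmm = fit_gmm(eligible_values(cm, maxd, log_transform),
                      log_transform=log_transform)
        sm = state_matrix(cm, gmm, max_dist_bins=maxd)
    track = compute_boundary_track(sm, params.d, params.t1, params.t2,
                                   params.d_p, params.min_prominence)
    ds, _ = assemble_domains(track.peaks, track.orientation, cm.n_bins,
                             cm.chrom, cm.resolution_bp)
    tads = _postprocess(ds.at_level(0), params, cm.resolution_bp, cm.n_bins,
                        sm, None)
    ds = DomainSet(tads, chrom=cm.chrom, resolution_bp=cm.resolution_bp,
                   n_bins=cm.n_bins)
    return ds, gap_intervals(ds, cm.n_bins)


def _min_domain_bins(min_domain_bp: int, resolution_bp: int) -> int:
    return max(1, int(np.ceil(min_domain_bp / resolution_bp)))


def call_hierarchy(
    cm: ContactMatrix,
    params: GmapParams | None = None,
    grid: ParamGrid | None = None,
    max_level: int = 2,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    min_domain_bp: int = DEFAULT_MIN_DOMAIN_BP,
    log_transform: bool = True,
    inherit_params: bool = False,
    sub_grid: ParamGrid | None = None,
) -> DomainSet:
    """Call TADs and recursively their nested subTADs.

    Level-0 TADs are called on the whole chromosome (tuned over ``grid``
    unless fixed ``params`` are given).  Each TAD at least twice the
    minimal domain size is re-processed on its own submatrix — fresh
    mixture fit, fresh statistics and (unless ``inherit_params``) a fresh
    grid search using the TAD itself as background.  Children smaller
    than the minimal domain size, or spanning the whole parent, are
    discarded.  Recursion stops at ``max_level``.
    """
    min_bins = _min_domain_bins(min_domain_bp, cm.resolution_bp)
    if params is None:
        tr = tune_parameters(cm, grid, max_dist_bp, min_domain_bp, log_transform)
        params = tr.best
    top, _ = call_domains(cm, params, log_transform)
    tads = [t for t in top.at_level(0) if t.size_bins >= min_bins]
    all_domains = list(tads)
    frontier = tads
    level = 0
    while level < max_level and frontier:
        children: list[Domain] = []
        for parent in frontier:
            kids = _call_subdomains(cm, parent, params, sub_grid, max_dist_bp,
                                    min_domain_bp, log_transform, inherit_params)
            children.extend(kids)
        all_domains.extend(children)
        frontier = children
        level += 1
    return DomainSet(all_domains, chrom=cm.chrom,
                     resolution_bp=cm.resolution_bp, n_bins=cm.n_bins)


def _call_subdomains(cm, parent, params, grid, max_dist_bp, min_domain_bp,
                     log_transform, inherit_params) -> list[Domain]:
    min_bins = _min_domain_bins(min_domain_bp, cm.resolution_bp)
    s, e = parent.start_bin, parent.end_bin
    size = e - s
    if size < 2 * min_bins:
        return []
    sub = ContactMatrix(cm.values[s:e, s:e].copy(), cm.resolution_bp,
                        chrom=cm.chrom, bin_offset=cm.bin_offset + s)
    maxd = max_dist_bins(cm.resolution_bp, max_dist_bp)
    try:
        vals = eligible_values(sub, maxd, log_transform)
        gmm = fit_gmm(vals, log_transform=log_transform)
    except ValueError:  # too few / degenerate values inside the TAD
        return []
    sm = state_matrix(sub, gmm, max_dist_bins=maxd)
    if inherit_params:
        best = params
    else:
        sub_grid = grid or SUBTAD_GRID
        usable_d = tuple(d for d in sub_grid.d if d < size)
        if not usable_d:
            usable_d = (max(2, size // 4),)
        sub_grid = replace(sub_grid, d=usable_d)
        sub_prom = None if params.min_prominence is None else min(
            params.min_prominence, 2.0)
        try:
            best = tune_parameters(sub, sub_grid, max_dist_bp, min_domain_bp,
                                   log_transform, sm=sm,
                                   min_prominence=sub_prom,
                                   prune_z=params.prune_z).best
        except ValueError:  # no peak survives t1 anywhere: recursion stops
            return []
    track = compute_boundary_track(sm, best.d, best.t1, best.t2, best.d_p,
                                   best.min_prominence)
    if not track.peaks:
        return []
    ds, _ = assemble_domains(track.peaks, track.orientation, sub.n_bins,
                             sub.chrom, sub.resolution_bp)
    cands = _postprocess(ds.at_level(0), best, sub.resolution_bp, sub.n_bins,
                         sm, None)
    kids = []
    for d in cands:
        if d.size_bins < min_bins:
            continue
        if d.start_bin == 0 and d.end_bin == size:
            continue  # not a subdivision of the parent
        kids.append(Domain(d.start_bin + s, d.end_bin + s,
                           level=parent.level + 1, parent=parent))
    return kids
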