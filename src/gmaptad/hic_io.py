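"""Contact-matrix and interval I/O.

Owns all coordinate conventions used by the package:

* bin indices are 0-based, half-open ``[start_bin, end_bin)``;
* genomic output is BED 0-based half-open, ``start_bp = start_bin * resolution``;
* contact matrices are symmetrized on load by averaging with the transpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "GenomicInterval",
    "Domain",
    "DomainSet",
    "read_contact_matrix",
    "write_domains_bed",
    "read_domains_bed",
    "read_bed_intervals",
]

_SYM_TOL = 1e-8


@dataclass
class ContactMatrix:
    """Normalized Hi-C contact matrix for one chromosome.

    Parameters
    ----------
    values
        Square, symmetric, nonnegative matrix of normalized contact
        frequencies (unitless).
    resolution_bp
        Bin width in base pairs.
    chrom
        Chromosome label used in genomic output.
    bin_offset
        Genomic start bin of row/column 0 (for sub-chromosome matrices).
    """

    values: np.ndarray
    resolution_bp: int
    chrom: str = "chr1"
    bin_offset: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix contains non-finite values")
        if np.any(v < 0):
            raise ValueError("contact matrix contains negative values")
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            warnings.warn(
                "asymmetric contact matrix symmetrized by (M + M.T)/2",
                stacklevel=3,
            )
        self.values = (v + v.T) / 2.0

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def unmappable_bins(self) -> np.ndarray:
        """Indices of bins with zero total contact (retained, just flagged)."""
        return np.flatnonzero(self.values.sum(axis=0) == 0)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start_bp, end_bp)."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.start_bp >= self.end_bp:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start_bp}-{self.end_bp}"
            )


@dataclass
class Domain:
    """A chromatin domain as a half-open bin interval.

    ``level`` 0 is a TAD; level k>0 domains are subTADs nested strictly
    inside their ``parent``.
    """

    start_bin: int
    end_bin: int
    level: int = 0
    parent: "Domain | None" = None

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("end_bin must exceed start_bin")
        if self.level < 0:
            raise ValueError("level must be >= 0")
        if self.parent is not None:
            if not (
                self.parent.start_bin <= self.start_bin
                and self.end_bin <= self.parent.end_bin
            ):
                raise ValueError("child domain must lie within its parent")

    @property
    def size_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class DomainSet:
    """Ordered collection of domains for one chromosome."""

    domains: list[Domain] = field(default_factory=list)
    chrom: str = "chr1"
    resolution_bp: int = 40_000
    n_bins: int = 0

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d.level, d.start_bin))
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        by_key: dict[tuple[int, int | None], list[Domain]] = {}
        for d in self.domains:
            by_key.setdefault((d.level, id(d.parent) if d.parent else None), []).append(d)
        for group in by_key.values():
            prev_end = -1
            for d in group:
                if d.start_bin < prev_end:
                    raise ValueError("overlapping domains at the same level")
                prev_end = d.end_bin

    def at_level(self, level: int) -> list[Domain]:
        return [d for d in self.domains if d.level == level]

    @property
    def max_level(self) -> int:
        return max((d.level for d in self.domains), default=-1)

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)


# ---------------------------------------------------------------------------
# Contact-matrix readers
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path,
    format: str = "dense",
    resolution_bp: int = 40_000,
    chrom: str = "chr1",
    n_bins: int | None = None,
) -> ContactMatrix:
    """Read a contact matrix from a dense or sparse 3-column text file.

    ``dense``: whitespace-delimited square matrix.  ``sparse3col``: lines
    of ``i j count`` with 0-based bin indices; entries are mirrored across
    the diagonal and missing entries are 0.  The matrix size is inferred
    from the maximum index + 1 unless ``n_bins`` overrides it.
    """
    if format == "dense":
        try:
            values = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"unparseable dense matrix file {path}: {exc}") from exc
        if values.shape[0] != values.shape[1]:
            raise ValueError(
                f"dense matrix in {path} is not square: shape {values.shape}"
            )
        if np.any(values < 0):
            raise ValueError(f"negative counts in {path}")
        return ContactMatrix(values, resolution_bp, chrom)

    if format == "sparse3col":
        rows: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'i j count', got {line!r}"
                    )
                try:
                    i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable line") from exc
                if i < 0 or j < 0:
                    raise ValueError(f"{path}:{lineno}: negative bin index")
                if c < 0:
                    raise ValueError(f"{path}:{lineno}: negative count")
                rows.append((i, j, c))
        if n_bins is None:
            n_bins = max((max(i, j) for i, j, _ in rows), default=-1) + 1
        values = np.zeros((n_bins, n_bins))
        for i, j, c in rows:
            values[i, j] = c
            values[j, i] = c
        return ContactMatrix(values, resolution_bp, chrom)

    raise ValueError(f"unknown format {format!r}; use 'dense' or 'sparse3col'")


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    """Write a dense whitespace-delimited matrix (integers kept integral)."""
    v = cm.values
    if np.allclose(v, np.round(v)):
        np.savetxt(path, v, fmt="%d")
    else:
        np.savetxt(path, v, fmt="%.6g")


# ---------------------------------------------------------------------------
# BED writers / readers
# ---------------------------------------------------------------------------

def _domain_names(ds: DomainSet) -> dict[int, str]:
    """Map id(domain) -> BED name: TAD_<i> / subTAD_<parent path>.<child idx>."""
    names: dict[int, str] = {}
    counters: dict[int | None, int] = {}
    for d in ds.domains:  # sorted by (level, start) so parents precede children
        key = id(d.parent) if d.parent is not None else None
        counters[key] = counters.get(key, 0) + 1
        idx = counters[key]
        if d.level == 0:
            names[id(d)] = f"TAD_{idx}"
        else:
            parent_name = names.get(id(d.parent), "orphan")
            path = parent_name.split("_", 1)[1] if "_" in parent_name else parent_name
            names[id(d)] = f"subTAD_{path}.{idx}"
    return names


def write_domains_bed(ds: DomainSet, path) -> None:
    """Write a DomainSet as BED4 (0-based half-open genomic coordinates)."""
    names = _domain_names(ds)
    res = ds.resolution_bp
    with open(path, "w") as fh:
        for d in ds.domains:
            start = d.start_bin * res
            end = d.end_bin * res
            fh.write(f"{ds.chrom}\t{start}\t{end}\t{names[id(d)]}\n")


def read_domains_bed(path, resolution_bp: int) -> DomainSet:
    """Parse a BED4 file written by :func:`write_domains_bed`.

    Bin indices are recovered exactly as ``bp // resolution``; hierarchy is
    rebuilt from the ``TAD_i`` / ``subTAD_i.j`` naming.
    """
    raw: list[tuple[str, int, int, str]] = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else f"TAD_{lineno}"
            raw.append((parts[0], int(parts[1]), int(parts[2]), name))
            chrom = chrom or parts[0]
    domains: list[Domain] = []
    by_path: dict[str, Domain] = {}
    # TADs first so subTAD parents exist regardless of file order
    for _, s, e, name in sorted(raw, key=lambda r: r[3].count(".")):
        level = name.count(".")
        sb, eb = s // resolution_bp, e // resolution_bp
        path_part = name.split("_", 1)[1] if "_" in name else name
        parent = None
        if level > 0:
            parent = by_path.get(path_part.rsplit(".", 1)[0])
        d = Domain(sb, eb, level=level, parent=parent)
        by_path[path_part] = d
        domains.append(d)
    n_bins = max((d.end_bin for d in domains), default=0)
    return DomainSet(domains, chrom=chrom or "chr1", resolution_bp=resolution_bp,
                     n_bins=n_bins)


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read genomic features (ChIP peaks, mutations, ...) from a BED file.

    Returns half-open 0-based intervals sorted by (chrom, start, end).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            out.append(GenomicInterval(chrom, start, end))
    out.sort(key=lambda iv: (iv.chrom, iv.start_bp, iv.end_bp))
    return out
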