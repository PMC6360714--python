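"""Reading pooled allele counts from mpileup / sync text and site filtering.

Pool-seq pipelines exchange per-position read counts in two text formats:
samtools mpileup (one coverage/bases/qualities column block per pool) and the
PoPoolation2 "sync" format (one ``A:T:C:G:N:del`` count field per pool).
This module parses both into :class:`SiteCounts`, applies the coverage and
allele-count filters used by windowed pool-seq estimators, and identifies
biallelic SNPs.

Conventions
-----------
* Internal allele order is always ``(A, C, G, T)``; sync files use
  ``A:T:C:G:N:del`` and the conversion is explicit.
* mpileup and sync positions are 1-based; all window/region arithmetic
  elsewhere in the package uses 0-based half-open intervals.
* ``N`` and deletion counts in sync input are ignored: coverage here means
  allele-informative reads.
* The mpileup quality column is ignored entirely; base-quality filtering is
  assumed to have happened upstream (or not at all).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: sync count fields are A:T:C:G:N:del; position of each internal
#: (A,C,G,T) allele within a sync field:
_INTERNAL_TO_SYNC = (0, 2, 3, 1)


class PileupParseError(ValueError):
    """Malformed mpileup/sync input, carrying the offending line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass(frozen=True)
class PoolSpec:
    """A sequenced pool: its label and the number of individuals pooled."""

    name: str
    n_individuals: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def haploid_size(self) -> int:
        """Number of chromosomes in the pool (n_individuals * ploidy)."""
        return self.n_individuals * self.ploidy


@dataclass
class SiteCounts:
    """Per-pool A/C/G/T read counts at one genomic position (1-based)."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # shape (n_pools, 4), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (n_pools, 4)")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool coverage (sum of the four allele counts)."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site filters: allele-count threshold and per-pool coverage bounds.

    ``min_count`` is applied to allele counts summed across pools, matching
    the PoPoolation2 convention; a pool passes coverage iff
    ``min_coverage <= coverage <= max_coverage`` and the site passes iff the
    fraction of passing pools is at least ``min_coverage_fraction``.
    """

    min_count: int = 3
    min_coverage: int = 10
    max_coverage: int = 100
    min_coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ValueError("need 0 < min_coverage <= max_coverage")
        if not (0.0 <= self.min_coverage_fraction <= 1.0):
            raise ValueError("min_coverage_fraction must be in [0, 1]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def _open_text(source: Union[str, IO[str]]) -> IO[str]:
    if isinstance(source, str):
        if source.endswith(".gz"):
            return gzip.open(source, "rt")
        return open(source, "rt")
    return source


def _count_bases(base_str: str, ref_idx: Optional[int]) -> np.ndarray:
    """Resolve one mpileup base string to (A,C,G,T) counts.

    '.'/',' count toward the reference base; '^' consumes the following
    mapping-quality character; '$' is skipped; '+k...'/'-k...' indel segments
    are skipped entirely; '*', 'N'/'n' and any other symbol contribute
    nothing.
    """
    counts = np.zeros(4, dtype=np.int64)
    i, n = 0, len(base_str)
    while i < n:
        c = base_str[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and base_str[j].isdigit():
                j += 1
            length = int(base_str[i + 1 : j]) if j > i + 1 else 0
            i = j + length
            continue
        if c in ".,":
            if ref_idx is not None:
                counts[ref_idx] += 1
        else:
            idx = BASE_INDEX.get(c.upper())
            if idx is not None:
                counts[idx] += 1
        i += 1
    return counts


def parse_mpileup(
    source: Union[str, IO[str], Iterable[str]], pools: Sequence[PoolSpec]
) -> Iterator[SiteCounts]:
    """Parse samtools mpileup text into per-pool allele counts.

    Each line must carry ``3 + 3 * n_pools`` tab-separated fields
    (chrom, pos, ref, then coverage/bases/qualities per pool, in the order
    given by ``pools``).  An unknown reference symbol is kept as ``N`` (the
    site is still emitted; '.'/',' then count nothing).

    Raises
    ------
    PileupParseError
        On a wrong field count or a non-numeric position, with line number.
    """
    n_pools = len(pools)
    expected = 3 + 3 * n_pools
    stream = _open_text(source) if isinstance(source, str) else source
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != expected:
            raise PileupParseError(
                line_no, f"expected {expected} fields, got {len(fields)}"
            )
        chrom = fields[0]
        try:
            pos = int(fields[1])
        except ValueError:
            raise PileupParseError(line_no, f"non-numeric position {fields[1]!r}")
        if pos < 1:
            raise PileupParseError(line_no, f"position must be >= 1, got {pos}")
        ref = fields[2].upper()
        if ref not in "ACGTN":
            ref = "N"
        ref_idx = BASE_INDEX.get(ref)
        counts = np.zeros((n_pools, 4), dtype=np.int64)
        for p in range(n_pools):
            base_str = fields[3 + 3 * p + 1]
            counts[p] = _count_bases(base_str, ref_idx)
        yield SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)


def read_sync(source: Union[str, IO[str], Iterable[str]]) -> Iterator[SiteCounts]:
    """Parse PoPoolation2 sync text (``chrom pos ref A:T:C:G:N:del`` per pool).

    N and deletion counts are dropped; coverage downstream means
    allele-informative reads only.
    """
    stream = _open_text(source) if isinstance(source, str) else source
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise PileupParseError(line_no, "sync line needs >= 4 fields")
        chrom = fields[0]
        try:
            pos = int(fields[1])
        except ValueError:
            raise PileupParseError(line_no, f"non-numeric position {fields[1]!r}")
        ref = fields[2].upper()
        if ref not in "ACGTN":
            ref = "N"
        n_pools = len(fields) - 3
        counts = np.zeros((n_pools, 4), dtype=np.int64)
        for p, tok in enumerate(fields[3:]):
            parts = tok.split(":")
            if len(parts) != 6:
                raise PileupParseError(
                    line_no, f"sync count field {tok!r} must have 6 ':'-parts"
                )
            try:
                vals = [int(v) for v in parts]
            except ValueError:
                raise PileupParseError(line_no, f"non-integer count in {tok!r}")
            for internal, sync_idx in enumerate(_INTERNAL_TO_SYNC):
                counts[p, internal] = vals[sync_idx]
        yield SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)


def write_sync(sites: Iterable[SiteCounts]) -> Iterator[str]:
    """Render SiteCounts as canonical sync lines (N and del written as 0)."""
    for site in sites:
        cols = [site.chrom, str(site.pos), site.ref]
        for p in range(site.n_pools):
            a, c, g, t = (int(x) for x in site.counts[p])
            cols.append(f"{a}:{t}:{c}:{g}:0:0")
        yield "\t".join(cols)


def classify_biallelic(
    site: SiteCounts, cfg: SiteFilterConfig
) -> tuple[Optional[tuple[int, int]], str]:
    """Classify a site as biallelic / monomorphic / multiallelic.

    Allele counts are summed across pools; alleles with combined count
    >= ``min_count`` are retained.  Returns ``((major, minor), "biallelic")``
    iff exactly two alleles are retained (major first, ties broken toward
    the alphabetically earlier base), else ``(None, reason)``.
    """
    combined = site.counts.sum(axis=0)
    retained = np.flatnonzero(combined >= cfg.min_count)
    if len(retained) < 2:
        return None, "monomorphic"
    if len(retained) > 2:
        return None, "multiallelic"
    a, b = retained
    if combined[b] > combined[a]:
        a, b = b, a
    return (int(a), int(b)), "biallelic"


def identify_biallelic(
    site: SiteCounts, cfg: SiteFilterConfig
) -> Optional[tuple[int, int]]:
    """Return (major, minor) allele indices iff the site is biallelic."""
    return classify_biallelic(site, cfg)[0]


def passes_coverage(
    site: SiteCounts, cfg: SiteFilterConfig
) -> tuple[bool, np.ndarray]:
    """Apply the per-pool coverage window and the coverage-fraction rule."""
    cov = site.coverage
    pool_ok = (cov >= cfg.min_coverage) & (cov <= cfg.max_coverage)
    frac = pool_ok.mean() if len(pool_ok) else 0.0
    return bool(frac >= cfg.min_coverage_fraction), pool_ok


# ---------------------------------------------------------------------------
# Columnar container for whole-dataset work


@dataclass
class SiteMatrix:
    """Columnar view of many sites: arrays instead of per-site objects.

    The windowed estimators and the region caller operate on this form; it is
    built once from any SiteCounts iterator.
    """

    chrom: np.ndarray  # object array of str
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # object array of single chars
    counts: np.ndarray  # (n_sites, n_pools, 4)
    pool_names: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_sites(
        cls, sites: Iterable[SiteCounts], pool_names: Sequence[str] = ()
    ) -> "SiteMatrix":
        chroms, poss, refs, cnts = [], [], [], []
        for s in sites:
            chroms.append(s.chrom)
            poss.append(s.pos)
            refs.append(s.ref)
            cnts.append(s.counts)
        if cnts:
            counts = np.stack(cnts)
        else:
            counts = np.zeros((0, len(pool_names) or 1, 4), dtype=np.int64)
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            counts=counts,
            pool_names=tuple(pool_names),
        )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def coverage(self) -> np.ndarray:
        """(n_sites, n_pools) coverage."""
        return self.counts.sum(axis=2)

    def site(self, i: int) -> SiteCounts:
        return SiteCounts(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            counts=self.counts[i],
        )

    def iter_sites(self) -> Iterator[SiteCounts]:
        for i in range(self.n_sites):
            yield self.site(i)


def coverage_mask(mat: SiteMatrix, cfg: SiteFilterConfig) -> np.ndarray:
    """Vectorised passes_coverage over a SiteMatrix -> boolean (n_sites,)."""
    cov = mat.coverage()
    pool_ok = (cov >= cfg.min_coverage) & (cov <= cfg.max_coverage)
    if mat.n_pools == 0:
        return np.zeros(mat.n_sites, dtype=bool)
    return pool_ok.mean(axis=1) >= cfg.min_coverage_fraction


def biallelic_table(
    mat: SiteMatrix, cfg: SiteFilterConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised biallelic classification.

    Returns ``(is_biallelic, major, minor)``; major/minor are allele indices
    into (A,C,G,T), valid only where ``is_biallelic``.
    """
    combined = mat.counts.sum(axis=1)  # (n_sites, 4)
    retained = combined >= cfg.min_count
    n_ret = retained.sum(axis=1)
    is_bi = n_ret == 2
    # stable argsort on -counts keeps base order for ties
    order = np.argsort(-combined, axis=1, kind="stable")
    major = order[:, 0]
    minor = order[:, 1]
    return is_bi, major, minor
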