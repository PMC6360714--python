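"""Dual-contrast percentile selection and candidate sweep-region calling.

Candidate regions for a trait shared by two populations but absent from a
close relative are defined by two simultaneous tail conditions on windowed
F_ST: the focal pair (e.g. the racing breed vs its non-racing relative) must
be ABOVE an upper empirical percentile, while the control pair (the two
racing breeds) must be BELOW a lower percentile.  Flagged windows closer
than a gap threshold (default 0.1 Mb, strict) are clustered; clusters with
fewer than two member windows or fewer than two distinct SNP positions are
discarded.

All inequalities are strict — a window exactly at a cutoff, or two windows
exactly 0.1 Mb apart, fail selection/merging.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContrastConfig",
    "CandidateRegion",
    "compute_thresholds",
    "select_windows",
    "cluster_windows",
    "filter_clusters",
    "summarize_regions",
    "regions_to_bed",
    "regions_to_tsv",
]


@dataclass(frozen=True)
class ContrastConfig:
    """Dual-contrast selection settings.

    ``upper_cut`` / ``lower_cut``, when given, pin the thresholds directly
    (e.g. to reproduce a published cutoff) and bypass percentile
    computation.
    """

    focal_pair: tuple[str, str]
    control_pair: tuple[str, str]
    upper_quantile: float = 0.95
    lower_quantile: float = 0.05
    cluster_gap: int = 100_000
    min_snps: int = 2
    upper_cut: Optional[float] = None
    lower_cut: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_quantile < self.upper_quantile < 1.0):
            raise ValueError("need 0 < lower_quantile < upper_quantile < 1")
        if self.cluster_gap <= 0:
            raise ValueError("cluster_gap must be > 0")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass
class Cluster:
    """An open cluster of flagged windows (pre-filtering)."""

    chrom: str
    start: int
    end: int
    windows: list[tuple[int, int]] = field(default_factory=list)
    focal_values: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class CandidateRegion:
    """A retained cluster of selected windows (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    n_snps: int
    max_focal_fst: float
    mean_focal_fst: float

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_thresholds(
    focal_values: Sequence[float],
    control_values: Sequence[float],
    cfg: ContrastConfig,
) -> tuple[float, float]:
    """Empirical percentile cutoffs (linear interpolation), or pinned values.

    The upper cutoff is the ``upper_quantile`` of the focal pair's defined
    window values; the lower cutoff is the ``lower_quantile`` of the control
    pair's.  Percentiles are taken over each pair's own defined windows.
    """
    if cfg.upper_cut is not None and cfg.lower_cut is not None:
        return float(cfg.upper_cut), float(cfg.lower_cut)
    focal = np.asarray(focal_values, dtype=np.float64)
    focal = focal[~np.isnan(focal)]
    control = np.asarray(control_values, dtype=np.float64)
    control = control[~np.isnan(control)]
    if focal.size == 0 or control.size == 0:
        raise ValueError("empty window table: cannot compute percentiles")
    upper = (
        float(cfg.upper_cut)
        if cfg.upper_cut is not None
        else float(np.quantile(focal, cfg.upper_quantile, method="linear"))
    )
    lower = (
        float(cfg.lower_cut)
        if cfg.lower_cut is not None
        else float(np.quantile(control, cfg.lower_quantile, method="linear"))
    )
    return upper, lower


def select_windows(
    focal_table: pd.DataFrame,
    control_table: pd.DataFrame,
    cuts: tuple[float, float],
) -> pd.DataFrame:
    """Flag windows with focal F_ST > upper cut AND control F_ST < lower cut.

    Both tables must share an identical (chrom, start, end) grid; windows
    with an undefined value in either pair are never selectable.  Both
    inequalities are strict.
    """
    upper, lower = cuts
    if len(focal_table) != len(control_table) or not (
        focal_table["chrom"].to_numpy() == control_table["chrom"].to_numpy()
    ).all() or not (
        focal_table["start"].to_numpy() == control_table["start"].to_numpy()
    ).all():
        raise ValueError("focal and control window grids differ")
    f = focal_table["value"].to_numpy(dtype=np.float64)
    c = control_table["value"].to_numpy(dtype=np.float64)
    flagged = (~np.isnan(f)) & (~np.isnan(c)) & (f > upper) & (c < lower)
    out = focal_table.loc[flagged, ["chrom", "start", "end", "n_snps", "value"]].copy()
    out = out.rename(columns={"value": "focal_fst"})
    out["control_fst"] = c[flagged]
    return out.reset_index(drop=True)


def cluster_windows(
    flagged: pd.DataFrame, cluster_gap: int = 100_000
) -> list[Cluster]:
    """Single-pass merge of flagged windows less than ``cluster_gap`` apart.

    Windows sorted by (chrom, start); a window joins the open cluster iff it
    is on the same chromosome and ``window.start - cluster.end <
    cluster_gap`` (strict).  Overlapping/adjacent windows merge trivially.
    """
    flagged = flagged.sort_values(["chrom", "start"]).reset_index(drop=True)
    clusters: list[Cluster] = []
    current: Optional[Cluster] = None
    for row in flagged.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        value = float(row.focal_fst) if hasattr(row, "focal_fst") else float("nan")
        if (
            current is not None
            and chrom == current.chrom
            and start - current.end < cluster_gap
        ):
            current.end = max(current.end, end)
            current.windows.append((start, end))
            current.focal_values.append(value)
        else:
            current = Cluster(
                chrom=chrom, start=start, end=end,
                windows=[(start, end)], focal_values=[value],
            )
            clusters.append(current)
    return clusters


def _count_cluster_snps(cluster: Cluster, snp_positions: np.ndarray) -> int:
    """Distinct SNP positions (1-based) inside any member window interval."""
    if len(snp_positions) == 0:
        return 0
    p0 = np.asarray(snp_positions, dtype=np.int64) - 1
    covered = np.zeros(len(p0), dtype=bool)
    for start, end in cluster.windows:
        covered |= (p0 >= start) & (p0 < end)
    return int(np.unique(p0[covered]).size)


def filter_clusters(
    clusters: Iterable[Cluster],
    snp_positions_by_chrom: dict[str, np.ndarray],
    min_snps: int = 2,
    min_windows: int = 2,
) -> list[CandidateRegion]:
    """Drop single-window clusters and clusters with too few distinct SNPs.

    SNPs shared by overlapping member windows are counted once.
    """
    regions: list[CandidateRegion] = []
    for cl in clusters:
        if len(cl.windows) < min_windows:
            continue
        snps = _count_cluster_snps(
            cl, snp_positions_by_chrom.get(cl.chrom, np.zeros(0, dtype=np.int64))
        )
        if snps < min_snps:
            continue
        vals = np.asarray(cl.focal_values, dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        regions.append(
            CandidateRegion(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                n_windows=len(cl.windows),
                n_snps=snps,
                max_focal_fst=float(vals.max()) if vals.size else float("nan"),
                mean_focal_fst=float(vals.mean()) if vals.size else float("nan"),
            )
        )
    return regions


# Genome size implied by a cumulative-region share of 1.9% for 46.39 Mb.
DEFAULT_GENOME_SIZE_BP = 2_442_000_000


def summarize_regions(
    regions: Sequence[CandidateRegion],
    genome_size_bp: int = DEFAULT_GENOME_SIZE_BP,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> dict:
    """Bookkeeping over called regions: counts, lengths, genome share.

    Regions must be non-overlapping (guaranteed by clustering).  Reports
    per-chromosome counts, each chromosome's share of all regions, and —
    when ``chrom_sizes`` is provided — regions per Mb as a second
    concentration measure.
    """
    regs = sorted(regions, key=lambda r: (r.chrom, r.start))
    for a, b in zip(regs, regs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("overlapping regions violate clustering contract")
    if not regs:
        return {
            "n_regions": 0,
            "min_length_bp": None,
            "max_length_bp": None,
            "mean_length_bp": None,
            "median_length_bp": None,
            "cumulative_length_bp": 0,
            "genome_fraction_pct": 0.0,
            "per_chromosome": {},
        }
    lengths = np.array([r.length for r in regs], dtype=np.float64)
    cumulative = int(lengths.sum())
    per_chrom: dict[str, dict] = {}
    for r in regs:
        d = per_chrom.setdefault(
            r.chrom, {"n_regions": 0, "cumulative_length_bp": 0}
        )
        d["n_regions"] += 1
        d["cumulative_length_bp"] += r.length
    for chrom, d in per_chrom.items():
        d["share_of_regions_pct"] = 100.0 * d["n_regions"] / len(regs)
        if chrom_sizes and chrom in chrom_sizes:
            d["regions_per_mb"] = d["n_regions"] / (chrom_sizes[chrom] / 1e6)
        else:
            d["regions_per_mb"] = None
    return {
        "n_regions": len(regs),
        "min_length_bp": float(lengths.min()),
        "max_length_bp": float(lengths.max()),
        "mean_length_bp": float(lengths.mean()),
        "median_length_bp": float(np.median(lengths)),
        "cumulative_length_bp": cumulative,
        "genome_fraction_pct": 100.0 * cumulative / genome_size_bp,
        "per_chromosome": per_chrom,
    }


def regions_to_bed(
    regions: Sequence[CandidateRegion], header: Optional[str] = None
) -> str:
    """BED (0-based half-open), score = max focal F_ST scaled to 0-1000."""
    lines = []
    if header:
        lines.append(f"# {header}")
    for i, r in enumerate(sorted(regions, key=lambda r: (r.chrom, r.start))):
        score = 0
        if np.isfinite(r.max_focal_fst):
            score = int(round(min(max(r.max_focal_fst, 0.0), 1.0) * 1000))
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i + 1}\t{score}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")


def regions_to_tsv(
    regions: Sequence[CandidateRegion], header: Optional[str] = None
) -> str:
    """Human-readable report with 1-based inclusive coordinates."""
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append(
        "chrom\tstart_1based\tend_1based\tlength_bp\tn_windows\tn_snps"
        "\tmax_focal_fst\tmean_focal_fst"
    )
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        lines.append(
            f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.length}\t{r.n_windows}"
            f"\t{r.n_snps}\t{r.max_focal_fst:.6g}\t{r.mean_focal_fst:.6g}"
        )
    return "\n".join(lines) + "\n"


def config_digest(obj) -> str:
    """Short stable hash of a JSON-serialisable config (output provenance)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
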