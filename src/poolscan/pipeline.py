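"""Glue running the scan end to end on an in-memory SiteMatrix.

The CLI, the test suite and the acceptance script all drive the pipeline
through :func:`run_scan`, so every stage (filtering, windowed statistics,
threshold computation, region calling, bookkeeping) is exercised through
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .pileup_io import PoolSpec, SiteFilterConfig, SiteMatrix
from .poolstats import (
    fst_window_table,
    genome_mean_pi_percent,
    pairwise_summary,
    pi_window_table,
    snp_table,
)
from .sweepcall import (
    CandidateRegion,
    ContrastConfig,
    cluster_windows,
    compute_thresholds,
    filter_clusters,
    select_windows,
    summarize_regions,
)

__all__ = ["WindowParams", "ScanResult", "run_scan"]


@dataclass(frozen=True)
class WindowParams:
    pi_size: int = 5000
    pi_covered_fraction: float = 0.5
    fst_size: int = 1000
    fst_step: int = 500
    #: windows with fewer usable SNPs have undefined F_ST (not selectable)
    fst_min_snps_window: int = 5


@dataclass
class ScanResult:
    snps: pd.DataFrame
    pi_tables: dict[str, pd.DataFrame]
    fst_tables: dict[tuple[str, str], pd.DataFrame]
    thresholds: tuple[float, float]
    flagged: pd.DataFrame
    regions: list[CandidateRegion]
    summary: dict = field(default_factory=dict)

    def fst_pair(self, a: str, b: str) -> pd.DataFrame:
        key = (a, b) if (a, b) in self.fst_tables else (b, a)
        return self.fst_tables[key]


def run_scan(
    mat: SiteMatrix,
    pools: list[PoolSpec],
    filter_cfg: SiteFilterConfig,
    contrast_cfg: ContrastConfig,
    windows: WindowParams = WindowParams(),
    chrom_lengths: Optional[dict[str, int]] = None,
    genome_size_bp: Optional[int] = None,
) -> ScanResult:
    """Filter sites, compute windowed statistics, call candidate regions."""
    if mat.n_sites == 0:
        raise ValueError("no sites in input")
    names = [p.name for p in pools]
    if mat.n_pools != len(pools):
        raise ValueError("pool count mismatch between data and config")
    snps = snp_table(mat, filter_cfg)

    pi_tables = {
        name: pi_window_table(
            mat,
            filter_cfg,
            i,
            size=windows.pi_size,
            covered_fraction=windows.pi_covered_fraction,
            chrom_lengths=chrom_lengths,
        )
        for i, name in enumerate(names)
    }
    fst_tables = {
        (names[i], names[j]): fst_window_table(
            mat,
            filter_cfg,
            (i, j),
            size=windows.fst_size,
            step=windows.fst_step,
            chrom_lengths=chrom_lengths,
            snps=snps,
            min_snps_window=windows.fst_min_snps_window,
        )
        for i, j in combinations(range(len(names)), 2)
    }

    def get_pair(pair: tuple[str, str]) -> pd.DataFrame:
        if pair in fst_tables:
            return fst_tables[pair]
        rev = (pair[1], pair[0])
        if rev in fst_tables:
            return fst_tables[rev]
        raise KeyError(f"unknown pool pair {pair}")

    focal = get_pair(tuple(contrast_cfg.focal_pair))
    control = get_pair(tuple(contrast_cfg.control_pair))
    cuts = compute_thresholds(
        focal["value"].to_numpy(), control["value"].to_numpy(), contrast_cfg
    )
    flagged = select_windows(focal, control, cuts)
    clusters = cluster_windows(flagged, cluster_gap=contrast_cfg.cluster_gap)
    snp_pos_by_chrom = {
        str(chrom): grp["pos"].to_numpy(dtype=np.int64)
        for chrom, grp in snps.groupby("chrom")
    }
    regions = filter_clusters(
        clusters, snp_pos_by_chrom, min_snps=contrast_cfg.min_snps
    )

    total_bp = genome_size_bp
    if total_bp is None:
        if chrom_lengths:
            total_bp = sum(chrom_lengths.values())
        else:
            total_bp = int(
                sum(
                    mat.pos[mat.chrom == c].max()
                    for c in pd.unique(mat.chrom)
                )
            )
    summary = summarize_regions(regions, genome_size_bp=total_bp,
                                chrom_sizes=chrom_lengths)
    summary["thresholds"] = {"upper_cut": cuts[0], "lower_cut": cuts[1]}
    summary["n_flagged_windows"] = int(len(flagged))
    summary["n_snps"] = int(len(snps))
    summary["pi_percent"] = {
        name: genome_mean_pi_percent(tab) for name, tab in pi_tables.items()
    }
    fst_summ = {}
    for (a, b), tab in fst_tables.items():
        vals = tab["value"].to_numpy()
        if np.isfinite(vals).any():
            mean, median = pairwise_summary(vals)
        else:
            mean, median = float("nan"), float("nan")
        fst_summ[f"{a}__{b}"] = {"mean": mean, "median": median}
    summary["pairwise_fst"] = fst_summ
    return ScanResult(
        snps=snps,
        pi_tables=pi_tables,
        fst_tables=fst_tables,
        thresholds=cuts,
        flagged=flagged,
        regions=regions,
        summary=summary,
    )
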