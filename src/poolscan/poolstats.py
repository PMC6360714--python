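"""Windowed nucleotide diversity and Karlsson-method pairwise F_ST.

Nucleotide diversity (pi)
-------------------------
Per site and pool, pi is the unbiased read-sample heterozygosity
``2 x (C - x) / (C (C - 1))`` where ``C`` is the pool's coverage and ``x``
the minor-allele read count.  Window pi (default 5,000 bp, non-overlapping)
is the sum of site values over sites passing the coverage filters, divided
by the number of covered sites; a window is reported only when at least a
configurable fraction of its span is covered.  The genome mean is the
unweighted mean of window values and is conventionally quoted in percent.

Karlsson F_ST
-------------
For a biallelic site with major/minor read counts ``(a_i, b_i)`` and depth
``n_i = a_i + b_i`` in each of two pools, let

    h_i = a_i b_i / (n_i (n_i - 1))          (unbiased estimate of p_i q_i)
    N   = (a_1/n_1 - a_2/n_2)^2 - h_1/n_1 - h_2/n_2
    D   = N + h_1 + h_2

``N`` and ``D`` are unbiased estimators of ``(p_1 - p_2)^2`` and of
``(p_1 - p_2)^2 + p_1 q_1 + p_2 q_2`` respectively, so the window estimate
``F_ST = sum(N) / sum(D)`` (a ratio of sums, not a mean of ratios) converges
to 1 - lambda^t under pure drift with per-generation retention
``lambda = 1 - 1/(2 Ne)``.  Fixed differences give exactly 1; values may be
slightly negative and are deliberately not clamped, because downstream
region calling uses empirical percentiles of the raw distribution.

F_ST windows are 1,000 bp sliding with 50% overlap by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pileup_io import (
    SiteFilterConfig,
    SiteMatrix,
    biallelic_table,
    coverage_mask,
)

__all__ = [
    "SiteFst",
    "WindowStat",
    "site_pi",
    "site_fst_components",
    "window_fst",
    "sliding_windows",
    "snp_table",
    "pi_window_table",
    "fst_window_table",
    "genome_mean_pi_percent",
    "pairwise_summary",
]


@dataclass(frozen=True)
class SiteFst:
    """Per-site Karlsson F_ST components (window value = sum num / sum den)."""

    h1: float
    h2: float
    num: float
    den: float

    @property
    def fst(self) -> float:
        """Per-site ratio; informational only — windows use ratio of sums."""
        return self.num / self.den if self.den != 0 else float("nan")


@dataclass(frozen=True)
class WindowStat:
    """A genomic window with a statistic value (pi or pairwise F_ST)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps: int
    n_covered: int
    value: float
    stat_kind: str  # "pi" | "fst"
    pair: Optional[tuple[str, str]] = None


def site_pi(x: int, C: int) -> float:
    """Unbiased per-site heterozygosity 2x(C-x)/(C(C-1)); NaN when C < 2."""
    if C < 2:
        return float("nan")
    if not 0 <= x <= C:
        raise ValueError("need 0 <= x <= C")
    return 2.0 * x * (C - x) / (C * (C - 1))


def site_fst_components(
    a1: int, b1: int, a2: int, b2: int
) -> Optional[SiteFst]:
    """Karlsson per-site components from major/minor read counts per pool.

    Returns None when either pool has depth < 2 (the site is then excluded
    from the window sums).
    """
    n1 = a1 + b1
    n2 = a2 + b2
    if n1 < 2 or n2 < 2:
        return None
    h1 = a1 * b1 / (n1 * (n1 - 1))
    h2 = a2 * b2 / (n2 * (n2 - 1))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    return SiteFst(h1=h1, h2=h2, num=num, den=den)


def window_fst(components: Iterable[Optional[SiteFst]]) -> float:
    """Ratio-of-sums window F_ST; NaN when sum(den) == 0 (undefined)."""
    num = 0.0
    den = 0.0
    for comp in components:
        if comp is None:
            continue
        num += comp.num
        den += comp.den
    return num / den if den != 0 else float("nan")


def sliding_windows(
    positions: np.ndarray, size: int = 1000, step: Optional[int] = None
) -> list[tuple[int, int, np.ndarray]]:
    """Assign sorted 1-based positions to sliding windows tiling from 0.

    Windows start at offsets 0, step, 2*step, ...; a site at 1-based
    position p falls in every window whose half-open interval [start,
    start+size) contains p-1.  Returns (start, end, member_indices) for
    windows with at least one member.  Raises on unsorted input.
    """
    if step is None:
        step = size // 2
    if size % step != 0:
        raise ValueError("step must divide size")
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    p0 = positions - 1  # 0-based
    members: dict[int, list[int]] = {}
    k = size // step
    for d in range(k):
        m = p0 // step - d
        for idx in np.flatnonzero(m >= 0):
            members.setdefault(int(m[idx]), []).append(int(idx))
    out = []
    for m in sorted(members):
        out.append((m * step, m * step + size, np.array(sorted(members[m]))))
    return out


def snp_table(mat: SiteMatrix, cfg: SiteFilterConfig) -> pd.DataFrame:
    """Identify filtered biallelic SNPs across all pools of a SiteMatrix.

    One row per site passing both the coverage filters and biallelic
    identification, with columns ``chrom, pos, major, minor`` plus per-pool
    major/minor read counts ``a<i>, b<i>``.
    """
    cov_ok = coverage_mask(mat, cfg)
    is_bi, major, minor = biallelic_table(mat, cfg)
    keep = cov_ok & is_bi
    idx = np.flatnonzero(keep)
    data = {
        "chrom": mat.chrom[idx],
        "pos": mat.pos[idx],
        "major": major[idx],
        "minor": minor[idx],
    }
    rows = np.arange(mat.n_sites)[idx]
    for p in range(mat.n_pools):
        data[f"a{p}"] = mat.counts[rows, p, major[idx]]
        data[f"b{p}"] = mat.counts[rows, p, minor[idx]]
    return pd.DataFrame(data)


def _window_grid(chrom_len: int, size: int, step: int) -> np.ndarray:
    """Start offsets of all windows fully inside [0, chrom_len)."""
    if chrom_len < size:
        return np.zeros(0, dtype=np.int64)
    n = (chrom_len - size) // step + 1
    return np.arange(n, dtype=np.int64) * step


def fst_window_table(
    mat: SiteMatrix,
    cfg: SiteFilterConfig,
    pair: tuple[int, int],
    size: int = 1000,
    step: int = 500,
    chrom_lengths: Optional[dict[str, int]] = None,
    snps: Optional[pd.DataFrame] = None,
    min_snps_window: int = 5,
) -> pd.DataFrame:
    """Sliding-window Karlsson F_ST for one pool pair over a full grid.

    Returns one row per grid window (whole chromosome tiling) with columns
    ``chrom, start, end, n_snps, value``; windows with fewer than
    ``min_snps_window`` usable SNPs carry NaN so that different pairs share
    an identical, alignable grid and noise-dominated windows are never
    selectable (the SNP-level analog of requiring a fully covered window).
    """
    if size % step != 0:
        raise ValueError("step must divide size")
    if snps is None:
        snps = snp_table(mat, cfg)
    i, j = pair
    frames = []
    chroms = pd.unique(mat.chrom) if mat.n_sites else []
    for chrom in chroms:
        sub = snps[snps["chrom"] == chrom]
        clen = (
            chrom_lengths.get(str(chrom))
            if chrom_lengths and str(chrom) in chrom_lengths
            else int(mat.pos[mat.chrom == chrom].max())
        )
        starts = _window_grid(int(clen), size, step)
        nwin = len(starts)
        num_sum = np.zeros(nwin)
        den_sum = np.zeros(nwin)
        snp_cnt = np.zeros(nwin, dtype=np.int64)
        if len(sub):
            a1 = sub[f"a{i}"].to_numpy(dtype=np.float64)
            b1 = sub[f"b{i}"].to_numpy(dtype=np.float64)
            a2 = sub[f"a{j}"].to_numpy(dtype=np.float64)
            b2 = sub[f"b{j}"].to_numpy(dtype=np.float64)
            n1 = a1 + b1
            n2 = a2 + b2
            ok = (n1 >= 2) & (n2 >= 2)
            h1 = np.where(ok, a1 * b1 / np.maximum(n1 * (n1 - 1), 1), 0.0)
            h2 = np.where(ok, a2 * b2 / np.maximum(n2 * (n2 - 1), 1), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                num = (
                    np.where(ok, a1 / np.maximum(n1, 1) - a2 / np.maximum(n2, 1), 0.0)
                    ** 2
                    - np.where(ok, h1 / np.maximum(n1, 1), 0.0)
                    - np.where(ok, h2 / np.maximum(n2, 1), 0.0)
                )
            num = np.where(ok, num, 0.0)
            den = np.where(ok, num + h1 + h2, 0.0)
            p0 = sub["pos"].to_numpy(dtype=np.int64) - 1
            k = size // step
            for d in range(k):
                m = p0 // step - d
                valid = (m >= 0) & (m < nwin) & ok
                num_sum += np.bincount(m[valid], weights=num[valid], minlength=nwin)
                den_sum += np.bincount(m[valid], weights=den[valid], minlength=nwin)
                snp_cnt += np.bincount(m[valid], minlength=nwin)
        defined = (den_sum != 0) & (snp_cnt >= min_snps_window)
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(defined, num_sum / np.where(defined, den_sum, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + size,
                    "n_snps": snp_cnt,
                    "value": value,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "value"])
    return pd.concat(frames, ignore_index=True)


def pi_window_table(
    mat: SiteMatrix,
    cfg: SiteFilterConfig,
    pool: int,
    size: int = 5000,
    covered_fraction: float = 0.5,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Non-overlapping window nucleotide diversity for one pool.

    Sites passing the coverage filters contribute ``site_pi``; sites that are
    not identified SNPs contribute 0 but still count as covered.  The window
    value is the per-covered-site mean; windows with fewer than
    ``covered_fraction * size`` covered sites are dropped.
    """
    cov_ok = coverage_mask(mat, cfg)
    cov = mat.coverage()[:, pool].astype(np.float64)
    is_bi, _major, minor = biallelic_table(mat, cfg)
    pi_site = np.zeros(mat.n_sites)
    rows = np.flatnonzero(cov_ok & is_bi)
    if len(rows):
        x = mat.counts[rows, pool, minor[rows]].astype(np.float64)
        C = cov[rows]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(C >= 2, 2.0 * x * (C - x) / np.maximum(C * (C - 1), 1), 0.0)
        pi_site[rows] = vals
    frames = []
    chroms = pd.unique(mat.chrom) if mat.n_sites else []
    for chrom in chroms:
        cmask = mat.chrom == chrom
        clen = (
            chrom_lengths.get(str(chrom))
            if chrom_lengths and str(chrom) in chrom_lengths
            else int(mat.pos[cmask].max())
        )
        nwin = max(int(clen) // size, 1) if clen >= size else 0
        if nwin == 0:
            continue
        p0 = mat.pos[cmask] - 1
        w = p0 // size
        ok = cov_ok[cmask] & (w < nwin)
        n_cov = np.bincount(w[ok], minlength=nwin)
        pi_sum = np.bincount(w[ok], weights=pi_site[cmask][ok], minlength=nwin)
        snp_in = np.bincount(w[ok & is_bi[cmask]], minlength=nwin)
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(n_cov > 0, pi_sum / np.maximum(n_cov, 1), np.nan)
        starts = np.arange(nwin, dtype=np.int64) * size
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + size,
                "n_snps": snp_in,
                "n_covered": n_cov,
                "value": value,
            }
        )
        df = df[df["n_covered"] >= covered_fraction * size]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "n_covered", "value"]
        )
    return pd.concat(frames, ignore_index=True)


def genome_mean_pi_percent(pi_table: pd.DataFrame) -> float:
    """Unweighted mean of window pi values, in percent; NaN if no windows."""
    if len(pi_table) == 0:
        return float("nan")
    return float(pi_table["value"].mean() * 100.0)


def pairwise_summary(values: Sequence[float]) -> tuple[float, float]:
    """Plain mean and median of defined window F_ST values.

    Raises on an empty (or all-NaN) input.
    """
    arr = np.asarray(values, dtype=np.float64)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined window values")
    return float(arr.mean()), float(np.median(arr))
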