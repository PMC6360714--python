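"""Three-population pooled-sequencing simulator with planted sweeps.

The generator emulates the study design the scan assumes: three horse pools
with a ((NSCT, NSD), SB) topology — the trotter (NSCT) and the draught
horse (NSD) share a recent split, the Standardbred (SB) an older one — plus
one-shot SB->NSCT admixture and selective sweeps acting jointly on NSCT and
SB.  Sites are unlinked allele frequencies pushed through Wright-Fisher
binomial drift; pooled read data are two-stage samples (pool allele count,
then reads with sequencing error).  This produces exactly the signal the
dual-contrast caller targets: high NSCT-vs-NSD, low NSCT-vs-SB F_ST inside
sweep spans.

Defaults: pools of 18/25/22 diploid individuals at mean coverages
44/36/56x; Ne = 500 per branch with branch lengths (t_deep 80, t_shallow
70 generations) and admixture fraction 0.15, chosen so the simulated mean
pairwise F_ST ordering is NSCT-NSD < NSCT-SB < NSD-SB with magnitudes near
0.07-0.11; 20 planted sweeps of 20 kb at s = 0.06 over 100 generations
(s*t = 6, near-fixation from standing variation) on a 10 Mb chromosome
carrying 80,000 ancestrally segregating sites — about 8 per kb before
drift absorption and site filtering, the density typical of pooled
cross-breed resequencing.

Everything is driven by one integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .pileup_io import BASES, SiteMatrix, write_sync

__all__ = [
    "SweepSpec",
    "SimConfig",
    "SimTruth",
    "draw_ancestral_freqs",
    "evolve_drift",
    "apply_admixture",
    "apply_sweep",
    "sample_pool_counts",
    "simulate",
    "emit_dataset",
    "default_sweeps",
]


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: center position (1-based), selection coefficient,
    and the span of co-selected sites around the center."""

    position: int
    s: float
    span_bp: int = 20_000

    @property
    def start(self) -> int:
        """0-based half-open start of the sweep span."""
        return max(self.position - 1 - self.span_bp // 2, 0)

    @property
    def end(self) -> int:
        return self.position - 1 + self.span_bp // 2


def default_sweeps(
    chrom_length_bp: int = 10_000_000,
    n_sweeps: int = 20,
    s: float = 0.06,
    span_bp: int = 20_000,
) -> tuple[SweepSpec, ...]:
    """Evenly spaced sweeps, kept away from chromosome ends."""
    centers = np.linspace(
        chrom_length_bp * 0.04, chrom_length_bp * 0.96, n_sweeps
    ).astype(int)
    return tuple(SweepSpec(position=int(c), s=s, span_bp=span_bp) for c in centers)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_sites: int = 80_000
    chrom: str = "sim1"
    chrom_length_bp: int = 10_000_000
    theta: float = 0.2
    Ne: int = 500
    t_deep: int = 80
    t_shallow: int = 70
    admix_m: float = 0.15
    sweep_t: int = 100
    sweep_loci: Optional[tuple[SweepSpec, ...]] = None
    pool_names: tuple[str, ...] = ("NSCT", "NSD", "SB")
    pool_sizes: tuple[int, ...] = (18, 25, 22)
    mean_coverages: tuple[float, ...] = (44.0, 36.0, 56.0)
    seq_error: float = 0.001
    n_filler: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_loci is None:
            self.sweep_loci = default_sweeps(self.chrom_length_bp)
        if not (0.0 <= self.admix_m <= 1.0):
            raise ValueError("admix_m must be in [0, 1]")
        if not (0.0 <= self.seq_error < 1.0):
            raise ValueError("seq_error must be in [0, 1)")
        if min(self.t_deep, self.t_shallow, self.sweep_t) < 0:
            raise ValueError("generation counts must be >= 0")
        if min(self.mean_coverages) <= 0:
            raise ValueError("mean coverages must be > 0")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["sweep_loci"] = [asdict(s) for s in self.sweep_loci]
        return d


@dataclass
class SimTruth:
    """Planted-sweep intervals and realized per-population frequencies."""

    chrom: str
    sweep_intervals: list[tuple[int, int]]  # 0-based half-open
    positions: np.ndarray  # 1-based SNP positions
    freqs: dict[str, np.ndarray]  # derived-allele freq per population
    ref_allele: np.ndarray  # base index per site
    alt_allele: np.ndarray

    def truth_bed(self) -> str:
        lines = [
            f"{self.chrom}\t{s}\t{e}\tsweep_{i + 1}"
            for i, (s, e) in enumerate(self.sweep_intervals)
        ]
        return "\n".join(lines) + ("\n" if lines else "")


def draw_ancestral_freqs(
    n_sites: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Ancestral derived-allele frequencies ~ Beta(theta, theta).

    Small theta gives the U-shaped spectrum of neutral standing variation;
    theta -> infinity concentrates at 0.5.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return rng.beta(theta, theta, size=n_sites)


def evolve_drift(
    freqs: np.ndarray, Ne: int, t: int, rng: np.random.Generator
) -> np.ndarray:
    """t rounds of Wright-Fisher binomial resampling of 2*Ne gametes.

    t = 0 is the identity; frequencies 0 and 1 are absorbing.
    """
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    p = np.asarray(freqs, dtype=np.float64).copy()
    n_gametes = 2 * Ne
    for _ in range(t):
        p = rng.binomial(n_gametes, p) / n_gametes
    return p


def apply_admixture(p_nsct: np.ndarray, p_sb: np.ndarray, m: float) -> np.ndarray:
    """One-shot admixture: p' = (1 - m) p_nsct + m p_sb."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must be in [0, 1]")
    return (1.0 - m) * np.asarray(p_nsct) + m * np.asarray(p_sb)


def apply_sweep(
    freq: np.ndarray, s: float, t: float, origin_freq: float = 1e-3
) -> np.ndarray:
    """Deterministic logistic selection trajectory over t generations.

    p_t = p0 e^{st} / (1 - p0 + p0 e^{st}); sites starting at 0 are seeded
    at ``origin_freq`` (a new favourable variant) before selection acts.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    p0 = np.asarray(freq, dtype=np.float64).copy()
    p0 = np.where(p0 == 0.0, origin_freq, p0)
    # logistic in decay form: stable for large s*t (exp underflows to 0)
    w = np.exp(-s * t)
    return p0 / (p0 + (1.0 - p0) * w)


def sample_pool_counts(
    freqs: np.ndarray,
    ref_allele: np.ndarray,
    alt_allele: np.ndarray,
    pool_size_individuals: int,
    mean_coverage: float,
    seq_error: float,
    rng: np.random.Generator,
    ploidy: int = 2,
) -> np.ndarray:
    """Two-stage pooled read sampling -> (n_sites, 4) base counts.

    Pool allele count ~ Binomial(ploidy * n_individuals, freq); coverage
    ~ Poisson(mean_coverage); alt reads ~ Binomial(C, pool frequency); each
    read is then flipped to a uniformly chosen other base with probability
    ``seq_error``.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    n_sites = len(freqs)
    n_chrom = ploidy * pool_size_individuals
    k = rng.binomial(n_chrom, freqs)
    pool_freq = k / n_chrom
    cov = rng.poisson(mean_coverage, size=n_sites)
    alt_reads = rng.binomial(cov, pool_freq)
    ref_reads = cov - alt_reads
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    if seq_error > 0:
        err_ref = rng.binomial(ref_reads, seq_error)
        err_alt = rng.binomial(alt_reads, seq_error)
        ref_reads = ref_reads - err_ref
        alt_reads = alt_reads - err_alt
        # distribute erroneous reads uniformly over the three other bases
        for reads_err, source in ((err_ref, ref_allele), (err_alt, alt_allele)):
            total = int(reads_err.sum())
            if total == 0:
                continue
            dest = rng.integers(0, 3, size=total)
            site_idx = np.repeat(np.arange(n_sites), reads_err)
            src = source[site_idx]
            # map 0..2 onto the three bases != src
            base = dest + (dest >= src)
            np.add.at(counts, (site_idx, base), 1)
    np.add.at(counts, (np.arange(n_sites), ref_allele), ref_reads)
    np.add.at(counts, (np.arange(n_sites), alt_allele), alt_reads)
    return counts


def _sample_positions(
    n: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """n distinct 1-based positions uniform on [1, length]."""
    if n > length:
        raise ValueError("more sites than positions")
    if n > length // 3:
        # dense sampling: rejection would thrash, permute instead
        return np.sort(rng.permutation(length)[:n].astype(np.int64)) + 1
    got: set[int] = set()
    out = np.zeros(0, dtype=np.int64)
    while len(got) < n:
        draw = rng.integers(1, length + 1, size=(n - len(got)) * 2)
        for v in draw:
            if len(got) >= n:
                break
            got.add(int(v))
    out = np.array(sorted(got), dtype=np.int64)
    return out


def simulate(cfg: SimConfig) -> tuple[SiteMatrix, SimTruth]:
    """Run the full generator in memory.

    Returns the pooled read counts (polymorphic sites plus monomorphic
    filler) as a SiteMatrix, and the truth table of planted sweeps and
    realized population frequencies at the polymorphic sites.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    positions = _sample_positions(n + cfg.n_filler, cfg.chrom_length_bp, rng)
    is_filler = np.zeros(len(positions), dtype=bool)
    filler_idx = rng.choice(len(positions), size=cfg.n_filler, replace=False)
    is_filler[filler_idx] = True
    snp_pos = positions[~is_filler]

    p_anc = draw_ancestral_freqs(n, cfg.theta, rng)
    # deep split: SB vs the (NSD, NSCT) ancestor
    p_sb = evolve_drift(p_anc, cfg.Ne, cfg.t_deep, rng)
    p_nn = evolve_drift(p_anc, cfg.Ne, cfg.t_deep, rng)
    # shallow split
    p_nsd = evolve_drift(p_nn, cfg.Ne, cfg.t_shallow, rng)
    p_nsct = evolve_drift(p_nn, cfg.Ne, cfg.t_shallow, rng)
    # SB -> NSCT admixture
    p_nsct = apply_admixture(p_nsct, p_sb, cfg.admix_m)
    # sweeps shared by NSCT and SB: the favourable variant arises (or is
    # standing) in SB, is carried into NSCT by the admixture pulse, and is
    # then selected in both breeds — so inside a sweep span both carry the
    # same selected-haplotype frequency.  NSD keeps its drifted frequency,
    # giving high focal-contrast and low control-contrast F_ST at the locus.
    sweep_intervals: list[tuple[int, int]] = []
    origin = 1.0 / (2 * cfg.Ne)
    for sw in cfg.sweep_loci:
        lo, hi = sw.start, sw.end
        sweep_intervals.append((lo, hi))
        in_span = (snp_pos - 1 >= lo) & (snp_pos - 1 < hi)
        if in_span.any():
            p_sel = apply_sweep(
                p_sb[in_span], sw.s, cfg.sweep_t, origin_freq=origin
            )
            p_sb[in_span] = p_sel
            p_nsct[in_span] = p_sel

    # allele identities: random ref base, random distinct alt base
    n_all = len(positions)
    ref_all = rng.integers(0, 4, size=n_all)
    alt_off = rng.integers(1, 4, size=n_all)
    alt_all = (ref_all + alt_off) % 4
    ref_snp = ref_all[~is_filler]
    alt_snp = alt_all[~is_filler]

    freqs_all = {name: np.zeros(n_all) for name in cfg.pool_names}
    pop_freqs = {"NSCT": p_nsct, "NSD": p_nsd, "SB": p_sb}
    counts = np.zeros((n_all, len(cfg.pool_names), 4), dtype=np.int64)
    for pi, name in enumerate(cfg.pool_names):
        f = np.zeros(n_all)
        f[~is_filler] = pop_freqs[name]
        freqs_all[name] = f
        counts[:, pi, :] = sample_pool_counts(
            f,
            ref_all,
            alt_all,
            cfg.pool_sizes[pi],
            cfg.mean_coverages[pi],
            cfg.seq_error,
            rng,
        )

    mat = SiteMatrix(
        chrom=np.array([cfg.chrom] * n_all, dtype=object),
        pos=positions,
        ref=np.array([BASES[i] for i in ref_all], dtype=object),
        counts=counts,
        pool_names=cfg.pool_names,
    )
    truth = SimTruth(
        chrom=cfg.chrom,
        sweep_intervals=sweep_intervals,
        positions=snp_pos,
        freqs={name: pop_freqs[name] for name in cfg.pool_names},
        ref_allele=ref_snp,
        alt_allele=alt_snp,
    )
    return mat, truth


def _mpileup_lines(mat: SiteMatrix, rng: np.random.Generator):
    """Render a SiteMatrix as mpileup text (deterministic base shuffling)."""
    for i in range(mat.n_sites):
        ref = str(mat.ref[i])
        cols = [str(mat.chrom[i]), str(int(mat.pos[i])), ref]
        for p in range(mat.n_pools):
            chars: list[str] = []
            for b in range(4):
                c = int(mat.counts[i, p, b])
                if c == 0:
                    continue
                sym = "." if BASES[b] == ref else BASES[b]
                chars.extend(sym * c)
            perm = rng.permutation(len(chars)) if chars else []
            bases = "".join(chars[j] for j in perm)
            cov = len(chars)
            quals = "I" * cov
            cols.extend([str(cov), bases if cov else "*", quals if cov else "*"])
        yield "\t".join(cols)


def emit_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write mpileup, sync, truth BED and a config echo; return file paths.

    Outputs are a deterministic function of the config (seed included).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat, truth = simulate(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # base-order shuffling only
    mpileup_path = out / "sim.mpileup"
    with open(mpileup_path, "w") as fh:
        for line in _mpileup_lines(mat, rng):
            fh.write(line + "\n")
    sync_path = out / "sim.sync"
    with open(sync_path, "w") as fh:
        for line in write_sync(mat.iter_sites()):
            fh.write(line + "\n")
    truth_path = out / "truth.bed"
    with open(truth_path, "w") as fh:
        fh.write(truth.truth_bed())
    cfg_path = out / "sim_config.json"
    with open(cfg_path, "w") as fh:
        json.dump(cfg.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "mpileup": str(mpileup_path),
        "sync": str(sync_path),
        "truth_bed": str(truth_path),
        "config": str(cfg_path),
        "n_sites": mat.n_sites,
    }
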