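"""Structured run configuration (YAML) shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .pileup_io import PoolSpec, SiteFilterConfig
from .pipeline import WindowParams
from .simdata import SimConfig, SweepSpec
from .sweepcall import DEFAULT_GENOME_SIZE_BP, ContrastConfig


@dataclass
class RunConfig:
    """Everything a run needs: pools, inputs, filters, windows, contrast."""

    pools: list[PoolSpec]
    mpileup: Optional[str] = None
    sync: Optional[str] = None
    filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    windows: WindowParams = field(default_factory=WindowParams)
    contrast: Optional[ContrastConfig] = None
    annotation_path: Optional[str] = None
    annotation_dialect: str = "bed"
    chrom_lengths: Optional[dict[str, int]] = None
    genome_size_bp: int = DEFAULT_GENOME_SIZE_BP
    outdir: str = "poolscan_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: Optional[SimConfig] = None
    raw: dict = field(default_factory=dict)


def _build_sim_config(d: dict[str, Any], seed: int) -> SimConfig:
    kwargs = dict(d)
    if "sweep_loci" in kwargs and kwargs["sweep_loci"] is not None:
        kwargs["sweep_loci"] = tuple(
            SweepSpec(**sw) for sw in kwargs["sweep_loci"]
        )
    for key in ("pool_names", "pool_sizes", "mean_coverages"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    kwargs.setdefault("seed", seed)
    return SimConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration.

    Minimal example::

        pools:
          - {name: NSCT, n_individuals: 18}
          - {name: NSD, n_individuals: 25}
          - {name: SB, n_individuals: 22}
        input: {sync: sim.sync}
        contrast:
          focal_pair: [NSCT, NSD]
          control_pair: [NSCT, SB]
        outdir: out
        seed: 1
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pools = [
        PoolSpec(
            name=p["name"],
            n_individuals=int(p["n_individuals"]),
            ploidy=int(p.get("ploidy", 2)),
        )
        for p in raw.get("pools", [])
    ]
    inp = raw.get("input", {}) or {}
    filt = SiteFilterConfig(**(raw.get("filters", {}) or {}))
    win = WindowParams(**(raw.get("windows", {}) or {}))
    contrast = None
    if raw.get("contrast"):
        c = dict(raw["contrast"])
        c["focal_pair"] = tuple(c["focal_pair"])
        c["control_pair"] = tuple(c["control_pair"])
        contrast = ContrastConfig(**c)
    ann = raw.get("annotation", {}) or {}
    seed = int(raw.get("seed", 0))
    sim = None
    if raw.get("simulate") is not None:
        sim = _build_sim_config(raw["simulate"] or {}, seed)
    chrom_lengths = raw.get("chrom_sizes") or None
    if chrom_lengths:
        chrom_lengths = {str(k): int(v) for k, v in chrom_lengths.items()}
    return RunConfig(
        pools=pools,
        mpileup=inp.get("mpileup"),
        sync=inp.get("sync"),
        filters=filt,
        windows=win,
        contrast=contrast,
        annotation_path=ann.get("path"),
        annotation_dialect=ann.get("dialect", "bed"),
        chrom_lengths=chrom_lengths,
        genome_size_bp=int(raw.get("genome_size_bp", DEFAULT_GENOME_SIZE_BP)),
        outdir=str(raw.get("outdir", "poolscan_out")),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        simulate=sim,
        raw=raw,
    )
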