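"""End-to-end orchestration: simulate -> filter -> stats -> scans, driven by
one config with a single master seed.

Named substreams are derived from the master seed so that every stochastic
stage (simulation, spacing filter, permutations) is independently
reproducible.  Each run writes a JSON manifest listing every artifact with
its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import IntervalSet, make_windows
from .io_formats import write_bed, write_panel, write_vcf
from .introgression import (direction_bias_test, f3_from_matrix,
                            scan_introgression)
from .sweep_scan import call_sweeps, permutation_fpr, qtl_overlap, \
    sweep_ratio_profile
from .popgen_stats import window_fst, window_pi
from .synthetic_data import IntrogressionPlan, SimConfig, simulate_genotypes
from .variant_filter import filter_cascade

log = logging.getLogger("cottonpop")

__all__ = ["RunConfig", "run_domestication_scan", "run_introgression_scan"]


def substream_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "cottonpop_run"
    seed: int = 0
    window_size: int = 100_000
    block_size: int = 1_000_000
    sweep_threshold: float = 25.0
    n_perm: int = 200
    min_accessions: int = 2
    maf: float = 0.05
    miss: float = 0.10
    min_gap: int = 10
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    sweeps: list = field(default_factory=list)        # (chrom,start,end)
    introgressions: list = field(default_factory=list)
    # each: (chrom,start,end,donor_species,[recipients])
    qtl_bed: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(seed=substream_seed(self.seed, "simulate"),
                        **self.sim)
        if self.sweeps:
            cfg.sweep_windows = IntervalSet.from_tuples(self.sweeps)
        if self.introgressions:
            cfg.introgression_events = [
                IntrogressionPlan(c, s, e, donor, list(recips))
                for c, s, e, donor, recips in self.introgressions]
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig, stage: str):
        self.out_dir = out_dir
        self.data = {"stage": stage, "seed": config.seed, "artifacts": {}}

    def add(self, name: str, path: Path):
        self.data["artifacts"][name] = {"path": str(path.name),
                                        "sha256": _sha256(path)}

    def write(self, extra: dict | None = None) -> dict:
        if extra:
            self.data.update(extra)
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return self.data


def _prepare(config: RunConfig, stage: str):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim_config()
    try:
        sim = simulate_genotypes(sim_cfg)
    except Exception as e:
        raise RuntimeError(f"[simulate] {e}") from e
    try:
        filtered = filter_cascade(sim.matrix, config.min_accessions,
                                  config.maf, config.miss, config.min_gap,
                                  substream_seed(config.seed, "spacing"))
    except Exception as e:
        raise RuntimeError(f"[filter] {e}") from e
    manifest = _Manifest(out, config, stage)
    write_vcf(filtered, out / "filtered.vcf", sim_cfg.layout)
    write_panel(filtered.panel, out / "panel.tsv")
    manifest.add("filtered_vcf", out / "filtered.vcf")
    manifest.add("panel", out / "panel.tsv")
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(
        {"sweeps": sim.truth["sweeps"],
         "introgressions": sim.truth["introgressions"],
         "seed": sim.truth["seed"]}, indent=2))
    manifest.add("truth", truth_path)
    return out, sim_cfg, filtered, manifest


def run_domestication_scan(config: RunConfig) -> dict:
    """filter -> windowed pi/F_ST -> ratio scan -> sweeps (+QTL overlap)."""
    out, sim_cfg, matrix, manifest = _prepare(config, "domestication_scan")
    panel = matrix.panel
    race = panel.ids_where(species="hirsutum", group="race")
    cult = panel.ids_where(species="hirsutum", group="cultivar")
    windows = make_windows(sim_cfg.layout, config.window_size)
    try:
        pi_r = window_pi(matrix, race, windows)
        pi_c = window_pi(matrix, cult, windows)
        fst = window_fst(matrix, panel.ids_where(species="hirsutum"),
                         panel.ids_where(species="barbadense"), windows)
        track = sweep_ratio_profile(pi_r, pi_c)
        sweeps = call_sweeps(track, config.sweep_threshold)
        fpr, _ = permutation_fpr(matrix, race, cult, windows,
                                 config.sweep_threshold, config.n_perm,
                                 substream_seed(config.seed, "permute"))
    except Exception as e:
        raise RuntimeError(f"[stats] {e}") from e
    track.to_csv(out / "ratio_track.tsv", sep="\t", index=False)
    fst.to_csv(out / "fst.tsv", sep="\t", index=False)
    bed = IntervalSet.from_tuples(
        [(s.chrom, s.start, s.end, f"sweep{k}")
         for k, s in enumerate(sweeps)]) if sweeps else IntervalSet()
    write_bed(bed, out / "sweeps.bed")
    manifest.add("ratio_track", out / "ratio_track.tsv")
    manifest.add("fst", out / "fst.tsv")
    manifest.add("sweeps_bed", out / "sweeps.bed")
    summary = {"n_sweeps": len(sweeps), "permutation_fpr": fpr,
               "n_sites_filtered": matrix.n_sites}
    if config.qtl_bed:
        from .io_formats import read_intervals
        rep = qtl_overlap(sweeps, read_intervals(config.qtl_bed))
        summary["sweeps_with_qtl"] = rep["sweeps_with_qtl"]
        summary["qtls_near_sweeps"] = rep["qtls_near_sweeps"]
    log.info("domestication scan: %s", summary)
    return manifest.write({"summary": summary})


def run_introgression_scan(config: RunConfig) -> dict:
    """filter -> block trees -> events -> direction bias + f3."""
    out, sim_cfg, matrix, manifest = _prepare(config, "introgression_scan")
    panel = matrix.panel
    outgroup = panel.ids_where(species="outgroup")
    if not outgroup:
        raise RuntimeError("[introgression] config has no outgroup "
                           "accessions")
    try:
        placed, events = scan_introgression(matrix, sim_cfg.layout,
                                            outgroup, config.block_size,
                                            config.min_accessions)
        n_gh_gb = sum(1 for e in events if e.direction == "Gh->Gb")
        n_gb_gh = len(events) - n_gh_gb
        bias = (direction_bias_test(n_gh_gb, n_gb_gh)
                if events else None)
        f3 = f3_from_matrix(
            matrix, panel.ids_where(species="barbadense"),
            panel.ids_where(species="hirsutum", group="race"), outgroup,
            block_size=max(20, matrix.n_sites // 40),
            labels=("Gb_cultivar", "Gh_race", "outgroup"))
    except Exception as e:
        raise RuntimeError(f"[introgression] {e}") from e
    ev_df = pd.DataFrame([{"chrom": e.chrom, "start": e.start,
                           "end": e.end, "direction": e.direction,
                           "subgenome": e.subgenome,
                           "n_accessions": e.n_accessions,
                           "recipients": ";".join(e.recipients)}
                          for e in events])
    ev_df.to_csv(out / "events.tsv", sep="\t", index=False)
    manifest.add("events", out / "events.tsv")
    summary = {"n_events": len(events), "n_gh_to_gb": n_gh_gb,
               "n_gb_to_gh": n_gb_gh,
               "direction_p_fisher": bias.p_fisher if bias else None,
               "direction_p_chi2": bias.p_chi2 if bias else None,
               "f3": f3.f3, "f3_z": f3.z}
    log.info("introgression scan: %s", summary)
    return manifest.write({"summary": summary})
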