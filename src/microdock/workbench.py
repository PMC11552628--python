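"""Configuration handling and the end-to-end docking orchestrator.

The pipeline mirrors the usual search-based docking workflow: parse receptor
and ligand, optionally compile user restraints into a hybrid scoring function,
run the chosen global sampler, cluster the sampled poses at 1.0 Angstrom RMSD,
re-rank the cluster representatives (optionally with a different scoring
function), and write the docked poses, a results table and a run log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .conformation import DockingBox
from .constraints import (DistanceConstraint, AtomSelector, constraint_as_sf,
                          read_matrix_constraint)
from .pdbqt import parse_pdbqt_ligand, parse_pdbqt_receptor, write_docked_poses
from .postprocess import DockingResult, cluster_poses, rerank, results_table
from .sampling import SamplerConfig, run_sampler
from .scoring import VinaScore, make_hybrid_sf
from .system import DockingSystem

__all__ = ["DockingConfig", "load_config", "run_docking", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class DockingConfig:
    """Resolved run configuration with the standard defaults (sampler mc,
    exhaustiveness 8, learning rate 0.1, 5 local-optimization steps,
    1.0 Angstrom cluster cutoff, empirical scoring)."""

    receptor: str = ""
    ligand: str = ""
    flex: str | None = None
    out_dir: str = "docked"
    center_x: float = 0.0
    center_y: float = 0.0
    center_z: float = 0.0
    size_x: float = 20.0
    size_y: float = 20.0
    size_z: float = 20.0
    sampler: str = "mc"
    scorer: str = "vinascore"
    exhaustiveness: int = 8
    steps: int = 60
    seed: int = 0
    lr: float = 0.1
    minimize_steps: int = 5
    minimize_method: str = "lbfgs"
    minimize_every: int = 1
    cluster_cutoff: float = 1.0
    num_modes: int = 9
    include_intra: bool = True
    rerank_scorer: str | None = None
    constraints: list = field(default_factory=list)
    constraint_weight: float = 0.5
    vina_weight: float = 0.5
    matrix_constraint: str | None = None
    allow_high_exhaustiveness: bool = False

    def box(self) -> DockingBox:
        return DockingBox(center=[self.center_x, self.center_y, self.center_z],
                          size=[self.size_x, self.size_y, self.size_z])


def load_config(path) -> DockingConfig:
    """Load a YAML/JSON-style mapping, fill defaults, reject unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in fields(DockingConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    cfg = DockingConfig(**data)
    _validate(cfg)
    return cfg


def _validate(cfg: DockingConfig) -> None:
    if cfg.sampler not in ("mc", "ga", "pso"):
        raise ConfigError(f"unknown sampler {cfg.sampler!r}")
    if cfg.scorer not in ("vinascore",):
        raise ConfigError(f"unknown scorer {cfg.scorer!r}")
    if cfg.exhaustiveness < 1:
        raise ConfigError("exhaustiveness must be >= 1")
    if cfg.exhaustiveness > 32 and not cfg.allow_high_exhaustiveness:
        raise ConfigError("exhaustiveness above the maximum of 32; set "
                          "allow_high_exhaustiveness to override")
    if cfg.cluster_cutoff <= 0:
        raise ConfigError("cluster_cutoff must be positive")


def _parse_constraint_entry(entry: dict) -> DistanceConstraint:
    a = entry.get("receptor")
    b = entry.get("ligand")
    if a is None or b is None:
        raise ConfigError("constraint entry needs 'receptor' and 'ligand' "
                          "selector mappings")
    sa = AtomSelector(side="receptor", chain=a.get("chain"),
                      residue_number=a.get("residue_number"),
                      atom_name=a.get("atom_name"), index=a.get("index"))
    sb = AtomSelector(side="ligand", chain=b.get("chain"),
                      residue_number=b.get("residue_number"),
                      atom_name=b.get("atom_name"), index=b.get("index"))
    return DistanceConstraint(
        a=sa, b=sb, kind=entry.get("kind", "harmonic"),
        target=entry.get("target"), lower=entry.get("lower"),
        upper=entry.get("upper"),
        force_constant=entry.get("force_constant", 1.0))


def build_scoring(cfg: DockingConfig, system: DockingSystem):
    """Empirical score, optionally hybridized with a constraint score."""
    vina = VinaScore(system, include_intra=cfg.include_intra)
    constraints = [_parse_constraint_entry(e) if isinstance(e, dict) else e
                   for e in cfg.constraints]
    if cfg.matrix_constraint:
        constraints.append(read_matrix_constraint(cfg.matrix_constraint))
    if not constraints:
        return vina
    costr = constraint_as_sf(constraints, system)
    return make_hybrid_sf([(vina, cfg.vina_weight),
                           (costr, cfg.constraint_weight)],
                          name="vina+constraints")


def run_docking(cfg: DockingConfig, system: DockingSystem | None = None
                ) -> DockingResult:
    """Parse -> (constraints -> hybrid) -> sample -> cluster -> re-rank ->
    write poses + results table + log. Returns the DockingResult."""
    _validate(cfg)  # configs may arrive from the CLI without load_config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t_start = time.perf_counter()
    timings = {}
    try:
        if system is None:
            stage = "parse"
            t0 = time.perf_counter()
            receptor = parse_pdbqt_receptor(
                Path(cfg.receptor).read_text(),
                Path(cfg.flex).read_text() if cfg.flex else None)
            ligand = parse_pdbqt_ligand(Path(cfg.ligand).read_text())
            system = DockingSystem(ligand, receptor, cfg.box())
            timings["parse"] = time.perf_counter() - t0

        stage = "scoring-setup"
        sf = build_scoring(cfg, system)

        stage = "sampling"
        t0 = time.perf_counter()
        sampler_cfg = SamplerConfig(
            strategy=cfg.sampler, exhaustiveness=cfg.exhaustiveness,
            steps_per_replica=cfg.steps, seed=cfg.seed,
            minimize_every=cfg.minimize_every,
            minimize_steps=cfg.minimize_steps, minimize_lr=cfg.lr,
            minimize_method=cfg.minimize_method,
            allow_high_exhaustiveness=cfg.allow_high_exhaustiveness)
        traces = run_sampler(system, sf, sampler_cfg)
        timings["sampling"] = time.perf_counter() - t0

        stage = "clustering"
        t0 = time.perf_counter()
        pool = []
        for tr in traces:
            for score, step, pose in tr.ranked_poses():
                pool.append((score, (tr.replica, step),
                             system.ligand_coords(pose)))
        reps = cluster_poses(pool, heavy_mask=system.ligand.heavy_mask,
                             cutoff=cfg.cluster_cutoff)
        timings["clustering"] = time.perf_counter() - t0

        stage = "reranking"
        sf_post = sf if cfg.rerank_scorer is None else _post_scorer(cfg, system)
        result = rerank(reps, sf_post, system, strategy=cfg.sampler,
                        exhaustiveness=cfg.exhaustiveness, seed=cfg.seed)
        result.poses = result.poses[:cfg.num_modes]

        stage = "output"
        poses_path = out_dir / "docked_poses.pdbqt"
        table_path = out_dir / "results.tsv"
        log_path = out_dir / "run.log"
        written.extend([poses_path, table_path, log_path])
        write_docked_poses([(rp.coords, rp.breakdown) for rp in result.poses],
                           system.ligand, poses_path)
        table_path.write_text(results_table(result))
        timings["total"] = time.perf_counter() - t_start
        log_lines = [f"seed: {cfg.seed}", "config:"]
        for f in fields(cfg):
            log_lines.append(f"  {f.name}: {getattr(cfg, f.name)!r}")
        log_lines.append("timings_s:")
        for key, val in timings.items():
            log_lines.append(f"  {key}: {val:.3f}")
        log_path.write_text("\n".join(log_lines) + "\n")
        result.extras["out_dir"] = str(out_dir)
        return result
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"docking failed during stage {stage!r}: {exc}") from exc


def _post_scorer(cfg: DockingConfig, system: DockingSystem):
    if cfg.rerank_scorer == "vinascore":
        return VinaScore(system, include_intra=cfg.include_intra)
    raise ConfigError(f"unknown rerank scorer {cfg.rerank_scorer!r}")
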