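"""Pose clustering, re-ranking and success-rate evaluation.

After global sampling, redundant poses are removed by greedy leader clustering
on heavy-atom RMSD (default cutoff 1.0 Angstrom): poses are visited in
ascending score order; a pose joins the first existing cluster whose
representative lies within the cutoff, otherwise it founds a new cluster.
Representatives can then be re-scored with a different ("post-processing")
scoring function and stably re-sorted, and per-target pose lists are summarised
with the standard top-N success rate (best pose among ranks 1..N with RMSD to
the reference below 2 Angstrom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conformation import heavy_atom_rmsd
from .scoring import ScoreBreakdown, ScoringFunction

__all__ = [
    "RankedPose",
    "DockingResult",
    "cluster_poses",
    "rerank",
    "top_n_success",
    "results_table",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedPose:
    coords: np.ndarray
    breakdown: ScoreBreakdown
    sampling_score: float
    cluster_id: int
    cluster_size: int = 1
    replica: int = -1
    step: int = -1
    rmsd_to_best: float = 0.0


@dataclass
class DockingResult:
    poses: list[RankedPose]
    strategy: str = ""
    exhaustiveness: int = 0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def best(self) -> RankedPose:
        return self.poses[0]


def cluster_poses(poses, heavy_mask=None, cutoff: float = 1.0):
    """Greedy leader clustering in ascending score order.

    ``poses`` is a sequence of ``(score, coords)`` or ``(score, tiebreak,
    coords)`` tuples over one shared topology. Returns a list of
    ``(score, tiebreak, coords, cluster_size)`` representatives in score order;
    no two representatives are within ``cutoff`` RMSD of each other.
    """
    items = []
    for p in poses:
        if len(p) == 2:
            score, coords = p
            tie = ()
        else:
            score, tie, coords = p[0], p[1], p[2]
            if not isinstance(tie, tuple):
                tie = (tie,)
        items.append((float(score), tie, np.asarray(coords, dtype=float)))
    items.sort(key=lambda t: (t[0], t[1]))
    reps: list[list] = []  # [score, tie, coords, size]
    for score, tie, coords in items:
        for rep in reps:
            if heavy_atom_rmsd(coords, rep[2], heavy_mask) <= cutoff:
                rep[3] += 1
                break
        else:
            reps.append([score, tie, coords, 1])
    return [(s, t, c, n) for s, t, c, n in reps]


def rerank(representatives, sf_post: ScoringFunction, system,
           strategy: str = "", exhaustiveness: int = 0,
           seed: int = 0) -> DockingResult:
    """Re-score cluster representatives with a post-processing scoring
    function and sort ascending (stable; sampling scores kept as metadata).
    A representative on which the scorer fails is dropped with a warning."""
    rec = system.receptor_coords()
    scored = []
    for cid, (score, tie, coords, size) in enumerate(representatives):
        try:
            bd = sf_post.evaluate(coords, rec)
        except Exception as exc:  # noqa: BLE001 - contract: drop and continue
            logger.warning("post-scoring failed for a pose (%s); dropped", exc)
            continue
        rp = RankedPose(coords=coords, breakdown=bd, sampling_score=score,
                        cluster_id=cid, cluster_size=size,
                        replica=tie[0] if len(tie) > 0 else -1,
                        step=tie[1] if len(tie) > 1 else -1)
        scored.append(rp)
    scored.sort(key=lambda rp: rp.breakdown.total)
    if scored:
        best = scored[0].coords
        for rp in scored:
            rp.rmsd_to_best = heavy_atom_rmsd(rp.coords, best,
                                              system.ligand.heavy_mask)
    return DockingResult(poses=scored, strategy=strategy,
                         exhaustiveness=exhaustiveness, seed=seed)


def top_n_success(per_target_rmsds, n: int, tau: float = 2.0) -> float:
    """Percentage of targets whose best pose among ranks 1..n has RMSD < tau.

    ``per_target_rmsds``: one ranked list of pose RMSDs per target.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    targets = list(per_target_rmsds)
    if not targets:
        raise ValueError("no targets supplied")
    hits = sum(1 for rmsds in targets
               if any(r < tau for r in list(rmsds)[:n]))
    return 100.0 * hits / len(targets)


def results_table(result: DockingResult) -> str:
    """Tab-separated summary: rank, post score, predicted free energy,
    sampling score, cluster id/size, RMSD to the top pose."""
    lines = ["rank\tscore\tpred_free_energy\tsampling_score\tcluster_id"
             "\tcluster_size\trmsd_to_best"]
    for rank, rp in enumerate(result.poses, start=1):
        lines.append(
            f"{rank}\t{rp.breakdown.total:.4f}\t"
            f"{rp.breakdown.predicted_free_energy:.3f}\t{rp.sampling_score:.4f}"
            f"\t{rp.cluster_id}\t{rp.cluster_size}\t{rp.rmsd_to_best:.3f}"
        )
    return "\n".join(lines) + "\n"
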