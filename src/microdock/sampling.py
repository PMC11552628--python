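"""Global pose search: Metropolis Monte Carlo with annealing, a genetic
algorithm over DOF chromosomes, and particle swarm optimization.

All three samplers run ``exhaustiveness`` independent replicas (default 8,
validated to at most 32 unless explicitly overridden), each seeded as
``master seed + replica index`` so results do not depend on execution order.
Replicas start from a pose drawn uniformly in the docking box and interleave
the global moves with short gradient-based local refinement whenever the
scoring function is differentiable.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conformation import PoseVector, wrap_angle
from .minimize import local_minimize
from .scoring import ScoringFunction
from .system import DockingSystem

__all__ = [
    "SamplerConfig",
    "SampleTrace",
    "metropolis_accept",
    "propose_move",
    "mc_search",
    "ga_search",
    "pso_search",
    "run_sampler",
]

_SEED_MOD = 2**31 - 1


@dataclass
class SamplerConfig:
    """Knobs shared by the three global samplers.

    ``steps_per_replica`` counts MC steps, or GA/PSO generations. The
    temperature schedule is geometric, ``T_i = T0 * decay**i``; ``t0=None``
    calibrates T0 per replica so that the initial uphill acceptance is roughly
    one half.
    """

    strategy: str = "mc"  # mc | ga | pso
    exhaustiveness: int = 8
    steps_per_replica: int = 60
    seed: int = 0
    minimize_every: int = 1
    minimize_steps: int = 30
    minimize_lr: float = 0.1
    minimize_method: str = "lbfgs"
    # MC move amplitudes and annealing
    sigma_translation: float = 1.0   # Angstrom
    sigma_rotation: float = 0.5      # radians
    sigma_torsion: float = 1.0       # radians
    global_move_prob: float = 0.3    # chance of a fresh uniform re-draw (mc)
    t0: float | None = None
    decay: float = 0.97
    # GA / PSO
    population: int = 32
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/dim
    elitism: int = 1
    refine_top: int = 3  # individuals/particles locally refined per generation
    immigrants: int = 2  # fresh random individuals injected per generation
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    # bookkeeping
    poses_per_replica: int = 10
    allow_high_exhaustiveness: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in ("mc", "ga", "pso"):
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")
        if self.exhaustiveness > 32 and not self.allow_high_exhaustiveness:
            raise ValueError("exhaustiveness above the default maximum of 32; "
                             "set allow_high_exhaustiveness to override")
        if self.steps_per_replica <= 0:
            raise ValueError("steps_per_replica must be > 0")
        if self.strategy in ("ga", "pso") and self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class SampleTrace:
    """Per-replica record: the best pose seen, the score history of the
    incumbent, and a small pool of the best distinct poses for clustering."""

    replica: int
    best_pose: PoseVector
    best_score: float
    accepted: int
    history: list = field(default_factory=list)
    top_poses: list = field(default_factory=list)  # [(score, step, PoseVector)]
    final_population: np.ndarray | None = None  # ga/pso diagnostic

    def record(self, score: float, step: int, pose: PoseVector, keep: int) -> None:
        heapq.heappush(self.top_poses, (-score, -step, _PoseBox(pose)))
        if len(self.top_poses) > keep:
            heapq.heappop(self.top_poses)

    def ranked_poses(self) -> list[tuple[float, int, PoseVector]]:
        out = [(-s, -n, box.pose) for s, n, box in self.top_poses]
        return sorted(out, key=lambda t: (t[0], t[1]))


class _PoseBox:
    """Opaque heap payload so heapq never compares PoseVectors."""

    __slots__ = ("pose",)

    def __init__(self, pose: PoseVector):
        self.pose = pose

    def __lt__(self, other):  # tie-break arbitrarily but deterministically
        return False


def metropolis_accept(delta: float, T: float, u: float) -> bool:
    """Accept a move of score change ``delta`` at temperature ``T`` given a
    uniform(0,1) draw ``u``: always downhill, uphill with prob exp(-delta/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta < 0:
        return True
    return u < np.exp(-delta / T)


def propose_move(pose: PoseVector, sigma_translation: float,
                 sigma_rotation: float, sigma_torsion: float,
                 rng: np.random.Generator) -> PoseVector:
    """Symmetric random-walk proposal: Gaussian translation, a rotation about
    a random axis by a Gaussian angle (composed with the current orientation),
    and a Gaussian kick to one uniformly chosen torsion/chi angle."""
    out = pose.copy()
    if sigma_translation > 0:
        out.translation = out.translation + rng.normal(0.0, sigma_translation, 3)
    if sigma_rotation > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, sigma_rotation)
        delta = Rotation.from_rotvec(axis * angle)
        out.orientation = (delta * Rotation.from_rotvec(out.orientation)).as_rotvec()
    n_ang = pose.k + sum(pose.chi_sizes)
    if sigma_torsion > 0 and n_ang > 0:
        pick = int(rng.integers(n_ang))
        kick = rng.normal(0.0, sigma_torsion)
        if pick < pose.k:
            out.torsions[pick] = wrap_angle(out.torsions[pick] + kick)
        else:
            pick -= pose.k
            for c in out.chi:
                if pick < len(c):
                    c[pick] = wrap_angle(c[pick] + kick)
                    break
                pick -= len(c)
    return out


def _replica_rng(config: SamplerConfig, replica: int) -> np.random.Generator:
    return np.random.default_rng((config.seed + replica) % _SEED_MOD)


def _calibrate_t0(system, sf, pose, score, config, rng) -> float:
    """Choose T0 so a typical initial uphill move is accepted ~50% of the time."""
    if config.t0 is not None:
        return config.t0
    deltas = []
    for _ in range(10):
        cand = system.clamp_to_box(propose_move(
            pose, config.sigma_translation, config.sigma_rotation,
            config.sigma_torsion, rng))
        d = system.score(cand, sf).total - score
        if np.isfinite(d) and d > 0:
            deltas.append(d)
    if not deltas:
        return 1.0
    return float(np.median(deltas) / np.log(2.0))


def mc_search(system: DockingSystem, sf: ScoringFunction,
              config: SamplerConfig) -> list[SampleTrace]:
    """Metropolis Monte Carlo with a geometric annealing schedule, interleaved
    with gradient-based local refinement of each proposal."""
    use_grad = sf.supports_gradient and config.minimize_every > 0
    traces = []
    for rep in range(config.exhaustiveness):
        rng = _replica_rng(config, rep)
        pose = system.random_pose(rng)
        score = system.score(pose, sf).total
        t = _calibrate_t0(system, sf, pose, score, config, rng)
        trace = SampleTrace(replica=rep, best_pose=pose.copy(),
                            best_score=score, accepted=0)
        trace.record(score, 0, pose.copy(), config.poses_per_replica)
        trace.history.append(score)
        for step in range(1, config.steps_per_replica + 1):
            if rng.random() < config.global_move_prob:
                # independence move: fresh pose anywhere in the box, which
                # (followed by minimization) probes a brand-new basin
                cand = system.random_pose(rng)
            else:
                cand = system.clamp_to_box(propose_move(
                    pose, config.sigma_translation, config.sigma_rotation,
                    config.sigma_torsion, rng))
            if use_grad and step % config.minimize_every == 0:
                cand, cand_score = local_minimize(
                    cand, sf, system, steps=config.minimize_steps,
                    lr=config.minimize_lr, method=config.minimize_method)
                clamped = system.clamp_to_box(cand)
                if not np.array_equal(clamped.translation, cand.translation):
                    cand = clamped
                    cand_score = system.score(cand, sf).total
            else:
                cand_score = system.score(cand, sf).total
            if metropolis_accept(cand_score - score, t, float(rng.random())):
                pose, score = cand, cand_score
                trace.accepted += 1
                trace.record(score, step, pose.copy(), config.poses_per_replica)
            if score < trace.best_score:
                trace.best_score = score
                trace.best_pose = pose.copy()
            trace.history.append(score)
            t = max(t * config.decay, 1e-6)
        traces.append(trace)
    return traces


def _mutation_sigmas(system: DockingSystem, config: SamplerConfig) -> np.ndarray:
    sig = np.empty(system.dim)
    sig[0:3] = config.sigma_translation
    sig[3:6] = config.sigma_rotation
    sig[6:] = config.sigma_torsion
    return sig


def _clamp_array(system: DockingSystem, x: np.ndarray) -> np.ndarray:
    pose = system.clamp_to_box(system.pose_from_array(x))
    out = x.copy()
    out[0:3] = pose.translation
    return out


def ga_search(system: DockingSystem, sf: ScoringFunction,
              config: SamplerConfig) -> list[SampleTrace]:
    """Genetic algorithm: the full DOF vector is the chromosome. Tournament
    selection, one-point crossover, per-gene Gaussian mutation, elitism, and
    local refinement of the elite when gradients are available."""
    if config.population < 2:
        raise ValueError("genetic algorithm needs a population of >= 2")
    dim = system.dim
    mut_rate = config.mutation_rate or 1.0 / dim
    sig = _mutation_sigmas(system, config)
    use_grad = sf.supports_gradient and config.minimize_every > 0
    traces = []
    for rep in range(config.exhaustiveness):
        rng = _replica_rng(config, rep)
        pop = np.array([system.random_pose(rng).to_array()
                        for _ in range(config.population)])
        fit = np.array([system.score_array(x, sf) for x in pop])
        trace = SampleTrace(replica=rep, best_pose=None, best_score=np.inf,
                            accepted=0)

        def note_best(gen):
            i = int(np.argmin(fit))
            if fit[i] < trace.best_score:
                trace.best_score = float(fit[i])
                trace.best_pose = system.pose_from_array(pop[i])
                trace.record(trace.best_score, gen,
                             trace.best_pose.copy(), config.poses_per_replica)
            trace.history.append(float(fit.min()))

        note_best(0)
        for gen in range(1, config.steps_per_replica + 1):
            # Lamarckian step: locally refine the fittest individuals and
            # write the improved chromosomes back into the gene pool
            if use_grad and gen % config.minimize_every == 0:
                for i in np.argsort(fit, kind="stable")[:config.refine_top]:
                    p, s = local_minimize(system.pose_from_array(pop[i]), sf,
                                          system, steps=config.minimize_steps,
                                          lr=config.minimize_lr,
                                          method=config.minimize_method)
                    if s < fit[i]:
                        pop[i], fit[i] = p.to_array(), s
            order = np.argsort(fit, kind="stable")
            elite = [pop[i].copy() for i in order[:config.elitism]]
            elite_fit = [float(fit[i]) for i in order[:config.elitism]]
            children = list(elite)
            child_fit = list(elite_fit)
            # random immigrants (locally refined) keep exploring new basins
            for _ in range(min(config.immigrants,
                               config.population - len(children))):
                imm = system.random_pose(rng)
                if use_grad:
                    p, s = local_minimize(imm, sf, system,
                                          steps=config.minimize_steps,
                                          lr=config.minimize_lr,
                                          method=config.minimize_method)
                    children.append(p.to_array())
                    child_fit.append(s)
                else:
                    children.append(imm.to_array())
                    child_fit.append(system.score_array(children[-1], sf))
            while len(children) < config.population:
                def tournament():
                    idx = rng.integers(config.population,
                                       size=config.tournament_size)
                    return pop[idx[np.argmin(fit[idx])]].copy()
                a, b = tournament(), tournament()
                if rng.random() < config.crossover_rate and dim > 1:
                    cut = int(rng.integers(1, dim))
                    a = np.concatenate([a[:cut], b[cut:]])
                mask = rng.random(dim) < mut_rate
                if mask.any():
                    a = a + mask * rng.normal(0.0, 1.0, dim) * sig
                    a[6:] = wrap_angle(a[6:])
                a = _clamp_array(system, a)
                children.append(a)
                child_fit.append(system.score_array(a, sf))
            pop = np.array(children[:config.population])
            fit = np.array(child_fit[:config.population])
            note_best(gen)
        trace.final_population = pop.copy()
        traces.append(trace)
    return traces


def pso_search(system: DockingSystem, sf: ScoringFunction,
               config: SamplerConfig) -> list[SampleTrace]:
    """Constriction-coefficient particle swarm: inertia plus cognitive and
    social pulls toward each particle's and the swarm's best positions.
    Angular DOFs are wrapped; the global best never worsens."""
    if config.population < 2:
        raise ValueError("particle swarm needs a population of >= 2")
    dim = system.dim
    sig = _mutation_sigmas(system, config)
    use_grad = sf.supports_gradient and config.minimize_every > 0
    traces = []
    for rep in range(config.exhaustiveness):
        rng = _replica_rng(config, rep)
        pos = np.array([system.random_pose(rng).to_array()
                        for _ in range(config.population)])
        vel = rng.normal(0.0, 0.25, size=pos.shape) * sig
        fit = np.array([system.score_array(x, sf) for x in pos])
        pbest = pos.copy()
        pbest_fit = fit.copy()
        gi = int(np.argmin(fit))
        gbest, gbest_fit = pos[gi].copy(), float(fit[gi])
        trace = SampleTrace(replica=rep,
                            best_pose=system.pose_from_array(gbest),
                            best_score=gbest_fit, accepted=0)
        trace.record(gbest_fit, 0, trace.best_pose.copy(),
                     config.poses_per_replica)
        trace.history.append(gbest_fit)

        def angular_diff(a, b):
            d = a - b
            d[..., 6:] = wrap_angle(d[..., 6:])
            return d

        for it in range(1, config.steps_per_replica + 1):
            r1 = rng.random(pos.shape)
            r2 = rng.random(pos.shape)
            vel = (config.inertia * vel
                   + config.cognitive * r1 * angular_diff(pbest, pos)
                   + config.social * r2 * angular_diff(gbest[None, :], pos))
            pos = pos + vel
            pos[:, 6:] = wrap_angle(pos[:, 6:])
            pos = np.array([_clamp_array(system, x) for x in pos])
            fit = np.array([system.score_array(x, sf) for x in pos])
            improved = fit < pbest_fit
            pbest[improved] = pos[improved]
            pbest_fit[improved] = fit[improved]
            gi = int(np.argmin(pbest_fit))
            if pbest_fit[gi] < gbest_fit:
                gbest, gbest_fit = pbest[gi].copy(), float(pbest_fit[gi])
            # re-seed the worst particles at fresh random positions (refined
            # when gradients are available) so the swarm keeps probing new
            # basins instead of collapsing early
            n_imm = min(config.immigrants, config.population)
            if n_imm:
                for i in np.argsort(fit, kind="stable")[::-1][:n_imm]:
                    imm = system.random_pose(rng)
                    if use_grad:
                        p, s = local_minimize(imm, sf, system,
                                              steps=config.minimize_steps,
                                              lr=config.minimize_lr,
                                              method=config.minimize_method)
                        pos[i] = p.to_array()
                        fit[i] = s
                    else:
                        pos[i] = imm.to_array()
                        fit[i] = system.score_array(pos[i], sf)
                    vel[i] = rng.normal(0.0, 0.1, dim) * sig
                    if fit[i] < pbest_fit[i]:
                        pbest[i] = pos[i].copy()
                        pbest_fit[i] = float(fit[i])
            gi = int(np.argmin(pbest_fit))
            if pbest_fit[gi] < gbest_fit:
                gbest, gbest_fit = pbest[gi].copy(), float(pbest_fit[gi])
            if use_grad and it % config.minimize_every == 0:
                # refine the current frontrunners and feed them back as
                # personal bests so the swarm is pulled toward refined minima
                for i in np.argsort(pbest_fit, kind="stable")[:config.refine_top]:
                    p, s = local_minimize(system.pose_from_array(pbest[i]), sf,
                                          system, steps=config.minimize_steps,
                                          lr=config.minimize_lr,
                                          method=config.minimize_method)
                    if s < pbest_fit[i]:
                        pbest[i], pbest_fit[i] = p.to_array(), float(s)
                gi = int(np.argmin(pbest_fit))
                if pbest_fit[gi] < gbest_fit:
                    gbest, gbest_fit = pbest[gi].copy(), float(pbest_fit[gi])
            if gbest_fit < trace.best_score:
                trace.best_score = gbest_fit
                trace.best_pose = system.pose_from_array(gbest)
                trace.record(gbest_fit, it, trace.best_pose.copy(),
                             config.poses_per_replica)
            trace.history.append(gbest_fit)
        trace.final_population = pos.copy()
        traces.append(trace)
    return traces


_SAMPLERS = {"mc": mc_search, "ga": ga_search, "pso": pso_search}


def run_sampler(system: DockingSystem, sf: ScoringFunction,
                config: SamplerConfig) -> list[SampleTrace]:
    lig = system.ligand
    extent = np.ptp(lig.reference_coords[lig.heavy_mask], axis=0)
    if np.any(extent > system.box.size):
        warnings.warn(
            "docking box is smaller than the ligand's extent; sampling "
            "proceeds with the root reference point confined to the box",
            stacklevel=2)
    return _SAMPLERS[config.strategy](system, sf, config)
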