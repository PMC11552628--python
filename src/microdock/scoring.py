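"""Differentiable empirical scoring.

The default scorer is the classic five-term empirical function of the
AutoDock Vina family, evaluated pairwise on heavy atoms within an 8 Angstrom
cutoff of the interatomic distance. With the surface distance
``s = d - R_i - R_j`` (R are per-type van der Waals radii):

    gauss1(s)      = exp(-(s / 0.5)^2)
    gauss2(s)      = exp(-((s - 3) / 2)^2)
    repulsion(s)   = s^2              for s < 0, else 0
    hydrophobic(s) = ramp down 1 -> 0 over s in [0.5, 1.5]  (both atoms apolar)
    hbond(s)       = ramp down 1 -> 0 over s in [-0.7, 0.0] (donor/acceptor pair)

The total is a weighted sum; the predicted binding free energy divides the
intermolecular part by ``1 + w_rot * N_rot`` (N_rot from the TORSDOF record) as
a torsional entropy normalisation. Every term is an explicit closed form, so
analytic gradients with respect to coordinates are available and are chained
through the kinematic map elsewhere.

Scoring functions are composable: :func:`make_hybrid_sf` builds a weighted
linear combination (used e.g. for half-and-half mixes of the empirical score
with a constraint score), and :func:`register_external_sf` wraps an arbitrary
user callable so that trained external models can drive sampling or re-ranking
without being reimplemented here.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from ._kernels import HAVE_NUMBA, vina_score_grad
from .pdbqt import XS_RADII

__all__ = [
    "VinaParams",
    "ScoreBreakdown",
    "ScoringFunction",
    "VinaScore",
    "HybridScoringFunction",
    "ExternalScoringFunction",
    "surface_distance",
    "vina_terms",
    "score_pose",
    "score_gradient",
    "make_hybrid_sf",
    "register_external_sf",
]

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


@dataclass
class VinaParams:
    """Weights, radii and cutoffs of the empirical scoring function. Defaults
    are the published values of the AutoDock Vina function; all of them are
    user-adjustable for Smina-style term customisation."""

    weights: dict = field(default_factory=lambda: {
        "gauss1": -0.035579,
        "gauss2": -0.005156,
        "repulsion": 0.840245,
        "hydrophobic": -0.035069,
        "hbond": -0.587439,
    })
    w_rot: float = 0.05846
    radii: dict = field(default_factory=lambda: dict(XS_RADII))
    cutoff: float = 8.0           # Angstrom, on the interatomic distance
    hydrophobic_range: tuple = (0.5, 1.5)   # surface distance, Angstrom
    hbond_range: tuple = (-0.7, 0.0)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[t] for t in TERM_NAMES])


@dataclass
class ScoreBreakdown:
    """A scalar score with its per-term decomposition.

    ``per_term`` holds the unweighted term sums, ``term_weights`` the weights,
    so ``total == sum(term_weights[t] * per_term[t])``. ``inter``/``intra`` are
    the weighted intermolecular and intramolecular parts; the predicted free
    energy (kcal/mol) derives from ``inter`` alone.
    """

    total: float
    per_term: dict
    term_weights: dict
    inter: float
    intra: float
    predicted_free_energy: float


def surface_distance(d, r_i, r_j):
    """Surface (shell-to-shell) distance ``d - r_i - r_j``; negative = clash."""
    return np.asarray(d) - r_i - r_j


def _ramp(s, lo, hi):
    """Piecewise-linear 1 -> 0 ramp: 1 for s <= lo, 0 for s >= hi."""
    return np.clip((hi - s) / (hi - lo), 0.0, 1.0)


def _ramp_deriv(s, lo, hi):
    s = np.asarray(s)
    return np.where((s > lo) & (s < hi), -1.0 / (hi - lo), 0.0)


def _raw_terms(s, params: VinaParams):
    """Unweighted term values at surface distance(s) ``s`` (vectorised).
    Gating by pair typing is applied by the caller."""
    s = np.asarray(s, dtype=float)
    g1 = np.exp(-((s / 0.5) ** 2))
    g2 = np.exp(-(((s - 3.0) / 2.0) ** 2))
    rep = np.where(s < 0.0, s * s, 0.0)
    phob = _ramp(s, *params.hydrophobic_range)
    hb = _ramp(s, *params.hbond_range)
    return g1, g2, rep, phob, hb


def _raw_term_derivs(s, params: VinaParams):
    s = np.asarray(s, dtype=float)
    g1 = np.exp(-((s / 0.5) ** 2))
    g2 = np.exp(-(((s - 3.0) / 2.0) ** 2))
    dg1 = -2.0 * s / 0.25 * g1
    dg2 = -2.0 * (s - 3.0) / 4.0 * g2
    drep = np.where(s < 0.0, 2.0 * s, 0.0)
    dphob = _ramp_deriv(s, *params.hydrophobic_range)
    dhb = _ramp_deriv(s, *params.hbond_range)
    return dg1, dg2, drep, dphob, dhb


def _terms_and_derivs(s, params: VinaParams):
    """Values and d/ds of all five terms in one pass (shared exponentials)."""
    s = np.asarray(s, dtype=float)
    g1 = np.exp(-((s / 0.5) ** 2))
    g2 = np.exp(-(((s - 3.0) / 2.0) ** 2))
    neg = s < 0.0
    rep = np.where(neg, s * s, 0.0)
    phob = _ramp(s, *params.hydrophobic_range)
    hb = _ramp(s, *params.hbond_range)
    dg1 = -8.0 * s * g1
    dg2 = -0.5 * (s - 3.0) * g2
    drep = np.where(neg, 2.0 * s, 0.0)
    dphob = _ramp_deriv(s, *params.hydrophobic_range)
    dhb = _ramp_deriv(s, *params.hbond_range)
    return (g1, g2, rep, phob, hb), (dg1, dg2, drep, dphob, dhb)


def vina_terms(d_surf, type_i: str, type_j: str,
               params: VinaParams | None = None) -> np.ndarray:
    """Unweighted five-term vector for one atom pair at surface distance
    ``d_surf``, gated on the pure per-type interaction flags."""
    from .pdbqt import assign_interaction_flags

    params = params or VinaParams()
    for t in (type_i, type_j):
        if t not in params.radii:
            raise KeyError(f"no van der Waals radius for atom type {t!r}")
    phob_i, _, acc_i = assign_interaction_flags(type_i)
    phob_j, _, acc_j = assign_interaction_flags(type_j)
    # without bond context, N/NA count as possible donors for the pure-type path
    don_i = type_i in ("N", "NA", "OA", "SA")
    don_j = type_j in ("N", "NA", "OA", "SA")
    g1, g2, rep, phob, hb = _raw_terms(d_surf, params)
    phob = phob if (phob_i and phob_j) else 0.0 * np.asarray(phob)
    hbond_pair = (don_i and acc_j) or (don_j and acc_i)
    hb = hb if hbond_pair else 0.0 * np.asarray(hb)
    return np.array([g1, g2, rep, phob, hb])


class ScoringFunction(ABC):
    """Contract: deterministic pose/coordinates -> scalar score with a
    per-term decomposition, optionally with coordinate gradients."""

    name: str = "sf"
    supports_gradient: bool = False
    weightable: bool = True

    @abstractmethod
    def evaluate(self, lig_coords: np.ndarray,
                 rec_coords: np.ndarray | None = None) -> ScoreBreakdown:
        ...

    def gradient(self, lig_coords: np.ndarray,
                 rec_coords: np.ndarray | None = None):
        """Return (dE/d lig_coords, dE/d rec_coords)."""
        raise NotImplementedError(
            f"{self.name} does not provide gradients; use a gradient-free sampler")

    def value_and_gradient(self, lig_coords: np.ndarray,
                           rec_coords: np.ndarray | None = None):
        """(total, dE/d lig_coords, dE/d rec_coords); subclasses may fuse the
        two computations for speed."""
        gl, gr = self.gradient(lig_coords, rec_coords)
        return self.evaluate(lig_coords, rec_coords).total, gl, gr


class _PairTables:
    """Precomputed per-pair radii sums and typing masks for one system."""

    def __init__(self, system, params: VinaParams):
        lig, rec = system.ligand, system.receptor
        self.idx_l = np.flatnonzero(lig.heavy_mask)
        self.idx_r = np.flatnonzero(rec.heavy_mask)
        radii = params.radii

        def atom_arrays(atoms, idx):
            r = np.array([radii[atoms[i].adtype] for i in idx])
            phob = np.array([atoms[i].is_hydrophobic for i in idx])
            don = np.array([atoms[i].is_hbond_donor for i in idx])
            acc = np.array([atoms[i].is_hbond_acceptor for i in idx])
            return r, phob, don, acc

        rl, phob_l, don_l, acc_l = atom_arrays(lig.atoms, self.idx_l)
        rr, phob_r, don_r, acc_r = atom_arrays(rec.atoms, self.idx_r)
        self.rsum_inter = rl[:, None] + rr[None, :]
        self.phob_inter = phob_l[:, None] & phob_r[None, :]
        self.hb_inter = (don_l[:, None] & acc_r[None, :]) | \
                        (acc_l[:, None] & don_r[None, :])

        # intra-ligand pairs: heavy atoms in different rigid fragments and at
        # least 4 bonds apart (1-2, 1-3 and 1-4 interactions excluded)
        frag = lig.fragment_ids
        gd = lig.bond_graph_distances()
        ii, jj = [], []
        hl = self.idx_l
        for a in range(len(hl)):
            for b in range(a + 1, len(hl)):
                i, j = hl[a], hl[b]
                if frag[i] != frag[j] and gd[i, j] >= 4:
                    ii.append(i)
                    jj.append(j)
        self.idx_l = np.ascontiguousarray(self.idx_l, dtype=np.int64)
        self.idx_r = np.ascontiguousarray(self.idx_r, dtype=np.int64)
        self.intra_i = np.array(ii, dtype=np.int64)
        self.intra_j = np.array(jj, dtype=np.int64)
        ri = np.array([radii[lig.atoms[i].adtype] for i in self.intra_i])
        rj = np.array([radii[lig.atoms[j].adtype] for j in self.intra_j])
        self.rsum_intra = ri + rj
        pi = np.array([lig.atoms[i].is_hydrophobic for i in self.intra_i], bool)
        pj = np.array([lig.atoms[j].is_hydrophobic for j in self.intra_j], bool)
        di = np.array([lig.atoms[i].is_hbond_donor for i in self.intra_i], bool)
        dj = np.array([lig.atoms[j].is_hbond_donor for j in self.intra_j], bool)
        ai = np.array([lig.atoms[i].is_hbond_acceptor for i in self.intra_i], bool)
        aj = np.array([lig.atoms[j].is_hbond_acceptor for j in self.intra_j], bool)
        self.phob_intra = pi & pj
        self.hb_intra = (di & aj) | (ai & dj)


class VinaScore(ScoringFunction):
    """The five-term empirical scoring function bound to one docking system."""

    supports_gradient = True

    def __init__(self, system, params: VinaParams | None = None,
                 include_intra: bool = True, name: str = "vinascore"):
        self.system = system
        self.params = params or VinaParams()
        self.include_intra = include_intra
        self.name = name
        self._tables = _PairTables(system, self.params)
        self._wvec = self.params.weight_vector()

    # -- helpers -----------------------------------------------------------

    def _pair_sums(self, lig_coords, rec_coords):
        """Unweighted inter and intra 5-term sums at the given coordinates."""
        t = self._tables
        p = self.params
        xl = lig_coords[t.idx_l]
        xr = rec_coords[t.idx_r]
        diff = xl[:, None, :] - xr[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        within = d <= p.cutoff
        s = d - t.rsum_inter
        g1, g2, rep, phob, hb = _raw_terms(s, p)
        phob = phob * t.phob_inter
        hb = hb * t.hb_inter
        inter = np.array([np.sum(x, where=within) for x in (g1, g2, rep, phob, hb)])

        if len(t.intra_i):
            dv = lig_coords[t.intra_i] - lig_coords[t.intra_j]
            di = np.sqrt(np.sum(dv * dv, axis=-1))
            wi = di <= p.cutoff
            si = di - t.rsum_intra
            g1i, g2i, repi, phobi, hbi = _raw_terms(si, p)
            phobi = phobi * t.phob_intra
            hbi = hbi * t.hb_intra
            intra = np.array([np.sum(x, where=wi)
                              for x in (g1i, g2i, repi, phobi, hbi)])
        else:
            intra = np.zeros(5)
        return inter, intra

    def evaluate(self, lig_coords, rec_coords=None) -> ScoreBreakdown:
        if rec_coords is None:
            rec_coords = self.system.receptor_coords()
        inter_terms, intra_terms = self._pair_sums(lig_coords, rec_coords)
        inter = float(self._wvec @ inter_terms)
        intra = float(self._wvec @ intra_terms)
        total = inter + (intra if self.include_intra else 0.0)
        per_term_terms = inter_terms + (intra_terms if self.include_intra else 0.0)
        n_rot = self.system.ligand.n_rot_torsdof
        fe = inter / (1.0 + self.params.w_rot * n_rot)
        return ScoreBreakdown(
            total=total,
            per_term=dict(zip(TERM_NAMES, per_term_terms.tolist())),
            term_weights=dict(self.params.weights),
            inter=inter, intra=intra, predicted_free_energy=fe,
        )

    def gradient(self, lig_coords, rec_coords=None):
        _, g_lig, g_rec = self.value_and_gradient(lig_coords, rec_coords)
        return g_lig, g_rec

    def value_and_gradient(self, lig_coords, rec_coords=None):
        """Fused score + coordinate gradient (shares the distance pass)."""
        if rec_coords is None:
            rec_coords = self.system.receptor_coords()
        t = self._tables
        if HAVE_NUMBA:
            p = self.params
            total, g_lig, g_rec = vina_score_grad(
                lig_coords, rec_coords, t.idx_l, t.idx_r, t.rsum_inter,
                t.phob_inter, t.hb_inter, t.intra_i, t.intra_j, t.rsum_intra,
                t.phob_intra, t.hb_intra, self._wvec, p.cutoff,
                p.hydrophobic_range[0], p.hydrophobic_range[1],
                p.hbond_range[0], p.hbond_range[1], self.include_intra)
            return total, g_lig, g_rec
        p = self.params
        w = self._wvec
        g_lig = np.zeros_like(lig_coords)
        g_rec = np.zeros_like(rec_coords)

        xl = lig_coords[t.idx_l]
        xr = rec_coords[t.idx_r]
        diff = xl[:, None, :] - xr[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        within = d <= p.cutoff
        s = d - t.rsum_inter
        (g1, g2, rep, phob, hb), (dg1, dg2, drep, dphob, dhb) = \
            _terms_and_derivs(s, p)
        phob = phob * t.phob_inter
        hb = hb * t.hb_inter
        total = float(np.sum(
            (w[0] * g1 + w[1] * g2 + w[2] * rep + w[3] * phob + w[4] * hb),
            where=within))
        dphob = dphob * t.phob_inter
        dhb = dhb * t.hb_inter
        dEdd = (w[0] * dg1 + w[1] * dg2 + w[2] * drep
                + w[3] * dphob + w[4] * dhb) * within
        safe_d = np.where(d > 1e-9, d, 1.0)
        gvec = (dEdd / safe_d)[:, :, None] * diff
        np.add.at(g_lig, t.idx_l, gvec.sum(axis=1))
        np.add.at(g_rec, t.idx_r, -gvec.sum(axis=0))

        if self.include_intra and len(t.intra_i):
            dv = lig_coords[t.intra_i] - lig_coords[t.intra_j]
            di = np.sqrt(np.sum(dv * dv, axis=-1))
            wi = di <= p.cutoff
            si = di - t.rsum_intra
            (g1, g2, rep, phob, hb), (dg1, dg2, drep, dphob, dhb) = \
                _terms_and_derivs(si, p)
            phob = phob * t.phob_intra
            hb = hb * t.hb_intra
            total += float(np.sum(
                (w[0] * g1 + w[1] * g2 + w[2] * rep + w[3] * phob
                 + w[4] * hb), where=wi))
            dphob = dphob * t.phob_intra
            dhb = dhb * t.hb_intra
            dEdd = (w[0] * dg1 + w[1] * dg2 + w[2] * drep
                    + w[3] * dphob + w[4] * dhb) * wi
            safe = np.where(di > 1e-9, di, 1.0)
            gv = (dEdd / safe)[:, None] * dv
            np.add.at(g_lig, t.intra_i, gv)
            np.add.at(g_lig, t.intra_j, -gv)
        return total, g_lig, g_rec


class HybridScoringFunction(ScoringFunction):
    """Weighted linear combination of scoring functions."""

    def __init__(self, components: list[tuple[ScoringFunction, float]],
                 name: str = "hybrid"):
        if not components:
            raise ValueError("a hybrid scoring function needs >= 1 component")
        for sf, wgt in components:
            if not np.isfinite(wgt):
                raise ValueError(f"non-finite weight for component {sf.name}")
        self.components = list(components)
        self.name = name
        self.supports_gradient = all(sf.supports_gradient
                                     for sf, _ in self.components)

    def evaluate(self, lig_coords, rec_coords=None) -> ScoreBreakdown:
        per_term: dict = {}
        weights: dict = {}
        total = inter = intra = 0.0
        fes = []
        for sf, wgt in self.components:
            bd = sf.evaluate(lig_coords, rec_coords)
            key = sf.name
            n = 2
            while key in per_term:  # disambiguate duplicate component names
                key = f"{sf.name}#{n}"
                n += 1
            per_term[key] = bd.total
            weights[key] = wgt
            total += wgt * bd.total
            inter += wgt * bd.inter
            intra += wgt * bd.intra
            if isinstance(sf, (VinaScore,)):
                fes.append(bd.predicted_free_energy)
        # report the physical component's free energy unweighted when there is
        # exactly one; otherwise fall back to the weighted total
        fe = fes[0] if len(fes) == 1 else (sum(fes) if fes else total)
        return ScoreBreakdown(total=total, per_term=per_term, term_weights=weights,
                              inter=inter, intra=intra, predicted_free_energy=fe)

    def gradient(self, lig_coords, rec_coords=None):
        if not self.supports_gradient:
            raise NotImplementedError(
                "not all hybrid components support gradients")
        g_lig = np.zeros_like(lig_coords)
        g_rec = None
        for sf, wgt in self.components:
            gl, gr = sf.gradient(lig_coords, rec_coords)
            g_lig = g_lig + wgt * gl
            if gr is not None:
                g_rec = (np.zeros_like(gr) if g_rec is None else g_rec) + wgt * gr
        return g_lig, g_rec

    def value_and_gradient(self, lig_coords, rec_coords=None):
        if not self.supports_gradient:
            raise NotImplementedError(
                "not all hybrid components support gradients")
        total = 0.0
        g_lig = np.zeros_like(lig_coords)
        g_rec = None
        for sf, wgt in self.components:
            val, gl, gr = sf.value_and_gradient(lig_coords, rec_coords)
            total += wgt * val
            g_lig = g_lig + wgt * gl
            if gr is not None:
                g_rec = (np.zeros_like(gr) if g_rec is None else g_rec) + wgt * gr
        return total, g_lig, g_rec


class ExternalScoringFunction(ScoringFunction):
    """A user-supplied scorer wrapped into the ScoringFunction contract."""

    def __init__(self, func, gradient_func=None, name: str = "external"):
        self.func = func
        self.gradient_func = gradient_func
        self.name = name
        self.supports_gradient = gradient_func is not None

    def evaluate(self, lig_coords, rec_coords=None) -> ScoreBreakdown:
        val = float(self.func(lig_coords, rec_coords))
        return ScoreBreakdown(total=val, per_term={self.name: val},
                              term_weights={self.name: 1.0}, inter=val,
                              intra=0.0, predicted_free_energy=val)

    def gradient(self, lig_coords, rec_coords=None):
        if self.gradient_func is None:
            return super().gradient(lig_coords, rec_coords)
        gl, gr = self.gradient_func(lig_coords, rec_coords)
        return np.asarray(gl, dtype=float), \
            None if gr is None else np.asarray(gr, dtype=float)


def make_hybrid_sf(components: list[tuple[ScoringFunction, float]],
                   name: str = "hybrid") -> HybridScoringFunction:
    """Compile a weighted combination of scoring functions (e.g. the empirical
    score and a constraint score at equal weights 0.5/0.5)."""
    return HybridScoringFunction(components, name=name)


def register_external_sf(func, gradient_func=None, name: str = "external",
                         probe_shape: tuple[int, int] = (2, 3),
                         probe_coords=None) -> ExternalScoringFunction:
    """Wrap ``func(lig_coords, rec_coords) -> float`` as a ScoringFunction.

    The callable is probed once at registration (on tiny zero coordinates, or
    on ``probe_coords = (lig, rec)`` for scorers that require realistic
    shapes); a raising callable is rejected immediately.
    """
    sf = ExternalScoringFunction(func, gradient_func, name=name)
    if probe_coords is None:
        probe_coords = (np.zeros((probe_shape[0], 3)),
                        np.zeros((probe_shape[0], 3)))
    try:
        val = sf.func(np.asarray(probe_coords[0], dtype=float),
                      np.asarray(probe_coords[1], dtype=float))
        float(val)
    except Exception as exc:
        raise ValueError(f"external scorer {name!r} failed a probe evaluation: "
                         f"{exc}") from exc
    return sf


def score_pose(lig_coords: np.ndarray, rec_coords: np.ndarray, system,
               params: VinaParams | None = None,
               include_intra: bool = True) -> ScoreBreakdown:
    """Score fixed Cartesian coordinates with the empirical function."""
    sf = VinaScore(system, params=params, include_intra=include_intra)
    return sf.evaluate(lig_coords, rec_coords)


def score_gradient(pose, sf: ScoringFunction, system) -> np.ndarray:
    """Gradient of ``sf`` composed with the kinematic map, with respect to
    every pose component (translation, orientation, torsions, chis)."""
    if not sf.supports_gradient:
        raise NotImplementedError(
            f"{sf.name} is not differentiable; use a gradient-free sampler")
    return system.pose_gradient(pose, sf)
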