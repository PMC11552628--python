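"""Gradient-based local refinement of the pose vector.

The score is treated as a loss over the (6+k [+chi]) pose vector and pushed
downhill for a small, fixed number of optimizer iterations (default: 5 steps
at learning rate 0.1). Because Adam and SGD are not monotone, the best pose
*visited* during the run is returned, so refinement can never return a pose
worse than its input.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .conformation import PoseVector, wrap_angle
from .scoring import ScoringFunction

__all__ = ["local_minimize", "minimize_vector"]

_METHODS = ("lbfgs", "adam", "sgd")


class _BestTracker:
    """Wraps an objective to remember the best (x, f) ever evaluated."""

    def __init__(self, fun):
        self.fun = fun
        self.best_x = None
        self.best_f = np.inf

    def __call__(self, x):
        f = self.fun(x)
        if np.isfinite(f) and f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        return f


def minimize_vector(x0: np.ndarray, fun=None, grad=None, steps: int = 5,
                    lr: float = 0.1, method: str = "lbfgs",
                    fun_and_grad=None, gtol: float = 1e-5,
                    ftol: float = 2.2e-9) -> tuple[np.ndarray, float]:
    """Run ``steps`` optimizer iterations on a plain vector objective and
    return the best visited point. ``steps = 0`` returns the input.

    Either ``fun``/``grad`` or a fused ``fun_and_grad`` (value, gradient) may
    be supplied; the fused form avoids recomputing shared work.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if fun_and_grad is None:
        if fun is None:
            raise ValueError("supply fun (and grad) or fun_and_grad")
        fun_and_grad = (None if grad is None
                        else (lambda x: (fun(x), grad(x))))
    if fun is None:
        fun = lambda x: fun_and_grad(x)[0]  # noqa: E731

    x = np.array(x0, dtype=float)
    tracked = _BestTracker(fun)
    f0 = tracked(x)
    if steps == 0:
        return x, f0

    if method == "lbfgs":
        def fg(z):
            f, g = fun_and_grad(z)
            if np.isfinite(f) and f < tracked.best_f:
                tracked.best_f = f
                tracked.best_x = np.array(z, dtype=float)
            return f, np.asarray(g, dtype=float)
        _scipy_minimize(fg, x, jac=True, method="L-BFGS-B",
                        options={"maxiter": steps, "maxcor": 10,
                                 "gtol": gtol, "ftol": ftol})
    else:
        m = np.zeros_like(x)
        v = np.zeros_like(x)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for step in range(1, steps + 1):
            _, g = fun_and_grad(x)
            g = np.asarray(g, dtype=float)
            if not np.all(np.isfinite(g)):
                warnings.warn("non-finite gradient during local refinement; "
                              "returning best pose so far", stacklevel=2)
                break
            if method == "sgd":
                x = x - lr * g
            else:  # adam
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** step)
                vhat = v / (1 - beta2 ** step)
                x = x - lr * mhat / (np.sqrt(vhat) + eps)
            tracked(x)
    if tracked.best_x is None:
        return np.array(x0, dtype=float), f0
    return tracked.best_x, tracked.best_f


def local_minimize(pose: PoseVector, sf: ScoringFunction, system,
                   steps: int = 5, lr: float = 0.1,
                   method: str = "adam") -> tuple[PoseVector, float]:
    """Refine a pose with a few iterations of a gradient-based optimizer.

    Angular components are left unwrapped during optimization (the score is
    2-pi periodic in them) and re-wrapped on return. Returns the best visited
    pose and its score; never worse than the input pose.
    """
    if not sf.supports_gradient:
        raise NotImplementedError(
            f"{sf.name} is not differentiable; local refinement needs gradients")
    x0 = pose.to_array()
    x, f = minimize_vector(
        x0,
        fun=lambda x: system.score_array(x, sf),
        fun_and_grad=lambda x: system.value_and_grad_array(x, sf),
        steps=steps, lr=lr, method=method,
    )
    out = system.pose_from_array(x)
    out.torsions = wrap_angle(out.torsions)
    out.chi = tuple(wrap_angle(c) for c in out.chi)
    return out, f
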