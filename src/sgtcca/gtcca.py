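"""Generalized tensor canonical correlation analysis (GTCCA).

Given one covariance tensor per correlation structure (a subset of views,
typically every subset that contains the phenotype view), GTCCA finds one
unit-norm canonical weight vector h_j per view maximizing the weighted sum
of squared structure correlations

    sum_m  a_m * rho_m^2,    rho_m = C_m x_1 h_{m1}^T x_2 ... x_k h_{mk}^T .

This is equivalent to jointly fitting a rank-1 approximation
rho_m * h_{m1} ∘ ... ∘ h_{mk} to every structure tensor by minimizing the
weighted sum of squared Frobenius residuals, which is solved here by
nonlinear conjugate gradient with the Dai-Yuan update and restart.

Gradients follow the matricized rank-1 factorization form: the derivative
of half the residual objective with respect to h_j is the matricized
residual times a Khatri-Rao product of the remaining weights, which for a
contracted implementation collapses to

    d/dh_j = sum_m a_m ( rho_m^2 * prod_{l != j} ||h_l||^2 * h_j
                         - rho_m * (C_m contracted over all modes but j) ).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tensor_core import CovarianceTensor

__all__ = [
    "StructureSpec",
    "GtccaProblem",
    "CanonicalSolution",
    "default_structures",
    "objective",
    "residual_objective",
    "gradient",
    "solve",
    "equivalence_check",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class StructureSpec:
    """A set of correlation structures (view-index tuples) with scalings."""

    structures: list[tuple[int, ...]]
    scalings: list[float] | None = None

    def __post_init__(self) -> None:
        self.structures = [tuple(s) for s in self.structures]
        for s in self.structures:
            if len(s) < 2:
                raise ValueError(f"structure {s} has fewer than 2 views")
            if len(set(s)) != len(s):
                raise ValueError(f"structure {s} repeats a view index")
        if len(set(self.structures)) != len(self.structures):
            raise ValueError("duplicate structures in spec")
        if self.scalings is None:
            self.scalings = [1.0] * len(self.structures)
        self.scalings = [float(a) for a in self.scalings]
        if len(self.scalings) != len(self.structures):
            raise ValueError("one scaling per structure required")
        if any(a < 0 for a in self.scalings):
            raise ValueError("scalings must be nonnegative")
        if not any(a > 0 for a in self.scalings):
            raise ValueError("at least one structure must have positive scaling")


@dataclass
class GtccaProblem:
    """Covariance tensors keyed by structure, plus view dimensions."""

    tensors: dict[tuple[int, ...], np.ndarray]
    dims: list[int]
    spec: StructureSpec
    _sq_norms: dict[tuple[int, ...], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean = {}
        for s in self.spec.structures:
            if s not in self.tensors:
                raise ValueError(f"no tensor supplied for structure {s}")
            t = self.tensors[s]
            if isinstance(t, CovarianceTensor):
                t = t.entries
            t = np.asarray(t, dtype=float)
            expect = tuple(self.dims[v] for v in s)
            if t.shape != expect:
                raise ValueError(f"tensor for {s} has shape {t.shape}, expected {expect}")
            clean[s] = t
        self.tensors = clean
        self._sq_norms = {s: float((t**2).sum()) for s, t in self.tensors.items()}

    @property
    def n_views(self) -> int:
        return len(self.dims)


@dataclass
class CanonicalSolution:
    weights: list[np.ndarray]
    rhos: dict[tuple[int, ...], float]
    objective_trace: list[float]
    converged: bool
    n_iter: int = 0


# --------------------------------------------------------------------------
# Structures
# --------------------------------------------------------------------------

def default_structures(k: int, phenotype_view: int) -> StructureSpec:
    """Every subset of views of size >= 2 containing the phenotype view."""
    if k < 2:
        raise ValueError("need at least 2 views")
    if not 0 <= phenotype_view < k:
        raise ValueError("phenotype view index out of range")
    others = [v for v in range(k) if v != phenotype_view]
    structures = []
    for m in range(len(others), 0, -1):
        for combo in itertools.combinations(others, m):
            structures.append(tuple(sorted(combo + (phenotype_view,))))
    return StructureSpec(structures)


# --------------------------------------------------------------------------
# Contractions
# --------------------------------------------------------------------------

def _contract_all(t: np.ndarray, hs: list[np.ndarray]) -> float:
    # singleton modes (the phenotype view) contribute a scalar factor and
    # are stripped as views, avoiding a full pass over the tensor
    scale = 1.0
    cur = t
    for h in reversed(hs):
        if h.size == 1:
            scale *= float(h[0])
            cur = cur[..., 0]
        else:
            cur = cur @ h
    return float(cur) * scale


def _contract_all_but(t: np.ndarray, hs: list[np.ndarray], skip: int) -> np.ndarray:
    cur = t
    for j in range(len(hs) - 1, skip, -1):
        cur = cur @ hs[j]
    for j in range(skip):
        cur = np.tensordot(cur, hs[j], axes=([0], [0]))
    return cur


def _trailing_contract(cur: np.ndarray, hs: list[np.ndarray]) -> np.ndarray:
    """Contract the trailing len(hs) modes with hs; singleton modes are
    stripped as views and folded in as scalar factors."""
    scale = 1.0
    for h in reversed(hs):
        if h.size == 1:
            scale *= float(h[0])
            cur = cur[..., 0]
        else:
            cur = cur @ h
    return cur * scale if scale != 1.0 else cur


def _leading_contract(cur: np.ndarray, hs: list[np.ndarray]) -> np.ndarray:
    scale = 1.0
    for h in hs:
        if h.size == 1:
            scale *= float(h[0])
            cur = cur[0]
        else:
            cur = np.tensordot(cur, h, axes=([0], [0]))
    return cur * scale if scale != 1.0 else cur


def _all_mode_contractions(t: np.ndarray, hs: list[np.ndarray]) -> list[np.ndarray]:
    """c_j = t contracted with every weight except h_j, for all j, sharing
    the drop of the last mode so the big tensor is traversed only twice."""
    k = len(hs)
    if k == 1:
        return [t.copy()]
    s = _trailing_contract(t, hs[-1:])  # last mode dropped once
    cs: list[np.ndarray] = []
    cur = s
    for j in range(k - 1):
        cs.append(np.atleast_1d(_trailing_contract(cur, hs[j + 1:k - 1])))
        if j < k - 2:
            cur = _leading_contract(cur, hs[j:j + 1])
    # c_{k-1}: contract the leading k-1 modes of the full tensor, keeping
    # the (possibly singleton) last mode untouched
    if hs[-1].size == 1:
        cs.append(np.atleast_1d(_leading_contract(t[..., 0], hs[:-1])))
    else:
        cs.append(np.atleast_1d(_leading_contract(t, hs[:-1])))
    return cs


def _structure_rhos(weights: list[np.ndarray], problem: GtccaProblem) -> dict[tuple[int, ...], float]:
    return {
        s: _contract_all(t, [weights[v] for v in s])
        for s, t in problem.tensors.items()
    }


def _check_unit(weights: list[np.ndarray], tol: float = 1e-6) -> None:
    for j, h in enumerate(weights):
        if abs(np.linalg.norm(h) - 1.0) > tol:
            raise ValueError(f"weight vector for view {j} is not unit norm")


# --------------------------------------------------------------------------
# Objectives and gradient
# --------------------------------------------------------------------------

def objective(weights: list[np.ndarray], problem: GtccaProblem) -> float:
    """Weighted sum of squared structure correlations (maximization form)."""
    _check_unit(weights)
    rhos = _structure_rhos(weights, problem)
    return float(sum(a * rhos[s] ** 2
                     for s, a in zip(problem.spec.structures, problem.spec.scalings)))


def residual_objective(
    weights: list[np.ndarray],
    rhos: dict[tuple[int, ...], float] | list[float],
    problem: GtccaProblem,
    check_unit: bool = True,
) -> float:
    """Weighted sum of squared Frobenius norms of the rank-1 residuals.

    Computed through the exact expansion
    ||C||^2 - 2*rho*<C, h1∘...∘hk> + rho^2 * prod ||h_l||^2.
    """
    if check_unit:
        _check_unit(weights)
    if not isinstance(rhos, dict):
        rhos = dict(zip(problem.spec.structures, rhos))
    total = 0.0
    for s, a in zip(problem.spec.structures, problem.spec.scalings):
        hs = [weights[v] for v in s]
        rho = rhos[s]
        inner = _contract_all(problem.tensors[s], hs)
        norm_prod = float(np.prod([h @ h for h in hs]))
        total += a * (problem._sq_norms[s] - 2.0 * rho * inner + rho**2 * norm_prod)
    return float(total)


@dataclass
class Gradient:
    h_grads: list[np.ndarray]
    rho_grads: dict[tuple[int, ...], float]

    @property
    def concatenated(self) -> np.ndarray:
        parts = [g.ravel() for g in self.h_grads]
        parts.append(np.array(list(self.rho_grads.values())))
        return np.concatenate(parts)


def gradient(
    weights: list[np.ndarray],
    rhos: dict[tuple[int, ...], float] | list[float],
    problem: GtccaProblem,
) -> Gradient:
    """Gradient of half the residual objective w.r.t. every h_j and rho_m.

    The half factor matches the matricized factorization form
    [Chat_(1) - C_(1)] * (rho * h_k ⊙ ... ⊙ h_2) for the weight gradients and
    (Chat - C) fully contracted for the correlation gradients; for a single
    pairwise structure with unit weights the latter reduces to
    rho - h1^T C h2.
    """
    if not isinstance(rhos, dict):
        rhos = dict(zip(problem.spec.structures, rhos))
    h_grads = [np.zeros_like(np.asarray(weights[j], float)) for j in range(problem.n_views)]
    rho_grads: dict[tuple[int, ...], float] = {}
    for s, a in zip(problem.spec.structures, problem.spec.scalings):
        hs = [np.asarray(weights[v], float) for v in s]
        t = problem.tensors[s]
        rho = float(rhos[s])
        sq = [float(h @ h) for h in hs]
        norm_prod = float(np.prod(sq))
        cs = _all_mode_contractions(t, hs)
        inner = float(cs[0] @ hs[0])
        for pos, v in enumerate(s):
            prod_others = norm_prod / sq[pos] if sq[pos] > 0 else float(
                np.prod([q for i, q in enumerate(sq) if i != pos]))
            h_grads[v] += a * (rho**2 * prod_others * hs[pos] - rho * cs[pos])
        rho_grads[s] = a * (rho * norm_prod - inner)
    return Gradient(h_grads, rho_grads)


# --------------------------------------------------------------------------
# Solver: nonlinear conjugate gradient, Dai-Yuan update with restart
# --------------------------------------------------------------------------

def _normalize_blocks(weights: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for h in weights:
        n = np.linalg.norm(h)
        out.append(h / n if n > 0 else h)
    return out


def _half_residual_at(weights: list[np.ndarray], problem: GtccaProblem) -> tuple[float, dict]:
    """Half residual objective at unit weights with closed-form rhos."""
    rhos = _structure_rhos(weights, problem)
    val = 0.5 * sum(
        a * (problem._sq_norms[s] - rhos[s] ** 2)
        for s, a in zip(problem.spec.structures, problem.spec.scalings)
    )
    return float(val), rhos


def _canonicalize_signs(weights: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for h in weights:
        i = int(np.argmax(np.abs(h)))
        out.append(-h if h[i] < 0 else h)
    return out


def solve(
    problem: GtccaProblem,
    init: list[np.ndarray] | str | None = None,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    obj_rel_tol: float = 1e-9,
) -> CanonicalSolution:
    """Solve GTCCA by minimizing the rank-1 factorization residual.

    Weights are kept unit-norm (renormalized after every accepted step, the
    norms absorbed into the closed-form correlations).  ``init`` may be a
    list of starting vectors, ``"random"`` (seeded unit vectors) or
    ``"svd"`` (warm start from the pairwise structures: each view starts at
    the normalized contraction of its largest pairwise tensor, falling back
    to random for views appearing in no pairwise structure).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dims = problem.dims

    if init is None or init == "random":
        weights = [rng.standard_normal(d) for d in dims]
    elif init == "svd":
        weights = _svd_init(problem, rng)
    else:
        weights = [np.asarray(h, float).copy() for h in init]
    weights = _normalize_blocks(weights)

    f, rhos = _half_residual_at(weights, problem)
    trace = [f]
    grad = np.concatenate(gradient(weights, rhos, problem).h_grads)
    d = -grad
    converged = False
    t_prev = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= grad_tol:
            converged = True
            break
        slope = float(grad @ d)
        if slope >= 0:  # restart: direction lost descent
            d = -grad
            slope = -gnorm**2
        # backtracking Armijo line search on the normalized iterates
        t = min(1.0, 2.0 * t_prev)
        accepted = False
        flat = np.concatenate(weights)
        offs = np.cumsum([0] + dims)
        for _ in range(40):
            cand_flat = flat + t * d
            cand = _normalize_blocks(
                [cand_flat[offs[j]:offs[j + 1]] for j in range(len(dims))])
            f_new, rhos_new = _half_residual_at(cand, problem)
            if f_new <= f + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        t_prev = t
        weights, f_old, f, rhos = cand, f, f_new, rhos_new
        trace.append(f)
        grad_new = np.concatenate(gradient(weights, rhos, problem).h_grads)
        denom = float(d @ (grad_new - grad))
        if abs(denom) > 1e-300:
            beta = float(grad_new @ grad_new) / denom  # Dai-Yuan
            d = -grad_new + beta * d
        else:
            d = -grad_new
        grad = grad_new
        if abs(f_old - f) <= obj_rel_tol * max(1.0, abs(f_old)):
            converged = True
            break
    if not converged:
        warnings.warn("GTCCA did not converge within max_iter; returning best iterate",
                      RuntimeWarning, stacklevel=2)

    weights = _canonicalize_signs(weights)
    rhos = _structure_rhos(weights, problem)
    return CanonicalSolution(weights, rhos, trace, converged, n_iter=it)


def _svd_init(problem: GtccaProblem, rng: np.random.Generator) -> list[np.ndarray]:
    """Warm start each view from its pairwise structures (leading singular
    vectors; for a d x 1 pairwise tensor this is the tensor itself)."""
    weights: list[np.ndarray | None] = [None] * problem.n_views
    best_sv = [0.0] * problem.n_views
    for s in problem.spec.structures:
        if len(s) != 2:
            continue
        u, sv, vt = np.linalg.svd(problem.tensors[s], full_matrices=False)
        for vec, v in ((u[:, 0], s[0]), (vt[0], s[1])):
            if weights[v] is None or sv[0] > best_sv[v]:
                weights[v] = vec.copy()
                best_sv[v] = float(sv[0])
    out = []
    for j, w in enumerate(weights):
        out.append(rng.standard_normal(problem.dims[j]) if w is None else w)
    return out


# --------------------------------------------------------------------------
# Theorem-equivalence check (test utility)
# --------------------------------------------------------------------------

def _unit_grid(d: int, resolution: int) -> list[np.ndarray]:
    if d == 1:
        return [np.array([1.0])]
    if d == 2:
        angles = np.linspace(0.0, np.pi, resolution, endpoint=False)
        return [np.array([np.cos(a), np.sin(a)]) for a in angles]
    if d == 3:
        pts = []
        for theta in np.linspace(0.0, np.pi, resolution, endpoint=False):
            for phi in np.linspace(0.0, np.pi, resolution, endpoint=False):
                pts.append(np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]))
        return pts
    raise ValueError("grid equivalence check supports d <= 3 only")


def equivalence_check(problem: GtccaProblem, grid_resolution: int = 60) -> dict:
    """Verify on a dense unit-sphere grid that maximizing sum a*rho^2 and
    minimizing the rank-1 residual pick the same weights (up to sign/grid).

    The residual at each grid point is evaluated by materializing the rank-1
    approximations with their closed-form correlations, independent of the
    algebraic shortcut used by the solver.
    """
    if any(d > 3 for d in problem.dims):
        raise ValueError("instance too large for grid equivalence check")
    grids = [_unit_grid(d, grid_resolution) for d in problem.dims]
    best_max, best_min = -np.inf, np.inf
    arg_max = arg_min = None
    for combo in itertools.product(*grids):
        weights = list(combo)
        rhos = _structure_rhos(weights, problem)
        obj = sum(a * rhos[s] ** 2
                  for s, a in zip(problem.spec.structures, problem.spec.scalings))
        res = 0.0
        for s, a in zip(problem.spec.structures, problem.spec.scalings):
            hs = [weights[v] for v in s]
            rank1 = rhos[s] * np.ones([1] * len(s))
            for pos, h in enumerate(hs):
                shape = [1] * len(s)
                shape[pos] = len(h)
                rank1 = rank1 * h.reshape(shape)
            res += a * float(((problem.tensors[s] - rank1) ** 2).sum())
        if obj > best_max:
            best_max, arg_max = obj, weights
        if res < best_min:
            best_min, arg_min = res, weights
    degenerate = bool(best_max <= 1e-14)
    cosines = [float(abs(a @ b)) for a, b in zip(arg_max, arg_min)]
    angle = max(float(np.arccos(np.clip(c, 0.0, 1.0))) for c in cosines)
    return {
        "argmax": arg_max,
        "argmin": arg_min,
        "max_objective": best_max,
        "min_residual": best_min,
        "max_angle_difference": angle,
        "grid_step": np.pi / grid_resolution,
        "degenerate": degenerate,
    }
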