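"""Sparsity via covariance-density-biased feature subsampling (SGTCCA).

Instead of a lasso-type penalty, sparsity comes from solving GTCCA on many
small feature subsets and scattering the per-subsample solutions into
canonical weight matrices H_j (one column per subsample, exact zeros for
features not sampled).  Subsets are drawn with probability increasing in
each feature's *covariance density* -- its total involvement in the
covariance tensors of the requested correlation structures -- so features
connected to other features or to the phenotype are more likely to enter.

The density itself is estimated cheaply: the full tensors are never built;
instead stratified permutation sweeps of small feature subsets are scored
for a number of iterations, per-feature tensor-entry sums are accumulated,
and the final density is the per-feature average over the iterations in
which a feature was sampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import gtcca
from .gtcca import GtccaProblem, StructureSpec
from .tensor_core import StandardizedBlock, covariance_tensor

log = logging.getLogger("sgtcca")

__all__ = [
    "SubsampleScheme",
    "CovarianceDensity",
    "CanonicalWeightMatrices",
    "estimate_covariance_density",
    "biased_subsample",
    "run_sgtcca",
]


@dataclass
class SubsampleScheme:
    """Parameters of the biased subsampling cascade.

    Defaults: 8% of features shared across subsamples, 2% distinct per
    subsample, 10 subsamples; density estimated from 10% uniform subsets
    over 50 iterations.
    """

    common_fraction: float = 0.08
    distinct_fraction: float = 0.02
    n_subsamples: int = 10
    density_subsample_fraction: float = 0.1
    density_iterations: int = 50
    bias_power: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.common_fraction <= 1:
            raise ValueError("common_fraction must be in (0, 1]")
        if not 0 <= self.distinct_fraction < 1:
            raise ValueError("distinct_fraction must be in [0, 1)")
        if self.common_fraction + self.distinct_fraction > 1:
            raise ValueError("common_fraction + distinct_fraction must be <= 1")
        if self.n_subsamples < 1:
            raise ValueError("need at least one subsample")
        if not 0 < self.density_subsample_fraction <= 1:
            raise ValueError("density_subsample_fraction must be in (0, 1]")
        if self.density_iterations < 1:
            raise ValueError("need at least one density iteration")
        if self.bias_power <= 0:
            raise ValueError("bias_power must be positive")


@dataclass
class CovarianceDensity:
    """Per-view nonnegative density vectors over features."""

    per_view: list[np.ndarray]

    def __post_init__(self) -> None:
        for v in self.per_view:
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError("density must be finite and nonnegative")


@dataclass
class CanonicalWeightMatrices:
    """H_j in R^{d_j x s} per view; column supports recorded per subsample."""

    matrices: list[np.ndarray]
    supports: list[list[np.ndarray]]  # supports[i][j]: sampled indices, subsample i view j
    converged: list[bool] = field(default_factory=list)
    density: CovarianceDensity | None = None

    @property
    def n_subsamples(self) -> int:
        return self.matrices[0].shape[1]


def _full_views(blocks: list[StandardizedBlock]) -> set[int]:
    """Views that are always fully included (the phenotype, d=1)."""
    return {j for j, b in enumerate(blocks) if b.n_features == 1}


def estimate_covariance_density(
    blocks: list[StandardizedBlock],
    spec: StructureSpec,
    scheme: SubsampleScheme,
    standardize_structures: bool = True,
) -> CovarianceDensity:
    """Estimate per-feature covariance density by uniform subsampling.

    Each iteration draws a uniform feature subset per view, builds the
    structure tensors on the subset, and credits every sampled feature with
    the sum of tensor entries involving it, over all structures containing
    its view; the final density averages over the iterations in which a
    feature was sampled.

    With ``standardize_structures`` (the default) each structure's
    per-feature contribution is z-scored across the sampled features before
    the structures are combined.  Raw entry sums live on wildly different
    scales (an order-k structure contributes ~prod d_m entries per feature,
    a pairwise one a single entry) and the rectified sampling-noise floor of
    the highest-order tensor drowns the discriminative lower-order
    contributions; standardizing puts every structure on a comparable scale.
    The combined z-score average is clipped at zero and a small floor (5% of
    the maximum) is added so that no feature is permanently frozen out of
    the biased sampling.  ``standardize_structures=False`` reproduces the
    plain summation.
    """
    rng = np.random.default_rng(scheme.seed)
    k = len(blocks)
    dims = [b.n_features for b in blocks]
    full = _full_views(blocks)
    sizes = []
    for j, d in enumerate(dims):
        m = d if j in full else int(round(scheme.density_subsample_fraction * d))
        if m < 1:
            raise ValueError(
                f"density_subsample_fraction leaves view {j} with no features")
        sizes.append(m)

    sums = [np.zeros(d) for d in dims]
    counts = [np.zeros(d) for d in dims]
    # stratified sweeps: each view's iterations chunk a fresh random
    # permutation, so every feature is observed once per sweep (same cost as
    # independent draws, but no feature is ever left unobserved)
    perms: list[np.ndarray | None] = [None] * k
    offsets = [0] * k

    def _next_chunk(j: int, d: int) -> np.ndarray:
        if perms[j] is None or offsets[j] + sizes[j] > d:
            perms[j] = rng.permutation(d)
            offsets[j] = 0
        out = perms[j][offsets[j]:offsets[j] + sizes[j]]
        offsets[j] += sizes[j]
        return out

    for _ in range(scheme.density_iterations):
        idx = [np.arange(d) if j in full else _next_chunk(j, d)
               for j, d in enumerate(dims)]
        sub = [b.values[:, idx[j]] for j, b in enumerate(blocks)]
        for s in spec.structures:
            t = covariance_tensor([sub[v] for v in s], view_indices=s).entries
            for pos, v in enumerate(s):
                axes = tuple(a for a in range(t.ndim) if a != pos)
                contrib = t.sum(axis=axes)
                if standardize_structures:
                    sd = contrib.std()
                    contrib = ((contrib - contrib.mean()) / sd
                               if sd > 1e-12 else np.zeros_like(contrib))
                sums[v][idx[v]] += contrib
        for j in range(k):
            counts[j][idx[j]] += 1

    per_view = []
    for j in range(k):
        dens = np.zeros(dims[j])
        seen = counts[j] > 0
        dens[seen] = sums[j][seen] / counts[j][seen]
        if standardize_structures:
            dens = np.maximum(dens, 0.0)
            if seen.any() and (~seen).any():
                dens[~seen] = dens[seen].mean()
            top = dens.max()
            dens = dens + (0.05 * top if top > 0 else 1.0)
        elif seen.any() and (~seen).any():
            # plain sums: unseen features get the mean observed density
            dens[~seen] = dens[seen].mean()
        per_view.append(dens)
    return CovarianceDensity(per_view)


def _weighted_draw(rng: np.random.Generator, pool: np.ndarray,
                   weights: np.ndarray, size: int) -> np.ndarray:
    """Draw ``size`` indices from ``pool`` without replacement, with
    probability proportional to ``weights`` (zero-weight entries are only
    used when the positive-weight pool is exhausted)."""
    if size >= pool.size:
        return pool.copy()
    w = np.asarray(weights, float)
    pos = w > 0
    if pos.sum() >= size:
        p = np.where(pos, w, 0.0)
        return rng.choice(pool, size=size, replace=False, p=p / p.sum())
    chosen = pool[pos]
    rest = rng.choice(pool[~pos], size=size - chosen.size, replace=False)
    return np.concatenate([chosen, rest])


def biased_subsample(
    density: CovarianceDensity,
    scheme: SubsampleScheme,
    blocks: list[StandardizedBlock],
) -> tuple[list[np.ndarray], list[list[np.ndarray]]]:
    """Draw the density-biased common and per-subsample distinct index sets.

    Returns ``(common, distinct)`` where ``common[j]`` holds the indices of
    view j shared by every subsample and ``distinct[i][j]`` the extra
    indices of subsample i.  Views of dimension 1 (the phenotype) are always
    fully included via the common set.  Sampling probabilities are
    proportional to density**bias_power (squared by default, in the spirit
    of leverage-score sampling, which sharpens the bias toward
    high-density features).
    """
    rng = np.random.default_rng(scheme.seed + 1)
    full = _full_views(blocks)
    dims = [b.n_features for b in blocks]
    dens = [np.asarray(v, float) ** scheme.bias_power for v in density.per_view]
    common: list[np.ndarray] = []
    remainders: list[np.ndarray] = []
    for j, d in enumerate(dims):
        if j in full:
            common.append(np.arange(d))
            remainders.append(np.array([], dtype=int))
            continue
        n_c = int(round(scheme.common_fraction * d))
        n_d = int(round(scheme.distinct_fraction * d))
        if n_c + n_d > d:
            raise ValueError(f"requested subsample sizes exceed view {j} size")
        pool = np.arange(d)
        c = np.sort(_weighted_draw(rng, pool, dens[j], n_c))
        common.append(c)
        remainders.append(np.setdiff1d(pool, c))
    distinct: list[list[np.ndarray]] = []
    for _ in range(scheme.n_subsamples):
        per_view = []
        for j, d in enumerate(dims):
            if j in full:
                per_view.append(np.array([], dtype=int))
                continue
            n_d = int(round(scheme.distinct_fraction * d))
            rem = remainders[j]
            per_view.append(np.sort(_weighted_draw(
                rng, rem, dens[j][rem], n_d)))
        distinct.append(per_view)
    return common, distinct


def run_sgtcca(
    blocks: list[StandardizedBlock],
    spec: StructureSpec,
    scheme: SubsampleScheme,
    density: CovarianceDensity | None = None,
    init: str = "svd",
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    center_tensors: bool = True,
    scale_structures: bool = True,
) -> CanonicalWeightMatrices:
    """Run the full SGTCCA cascade: density, biased subsampling, one GTCCA
    solve per subsample, scattered into sparse canonical weight matrices.

    ``blocks`` must include the phenotype as a (standardized) d=1 view.
    Each subsample's solve is seeded independently from the scheme seed, so
    runs are order-insensitive and reproducible.

    With ``center_tensors`` (default) each structure tensor is centered
    (its mean entry subtracted) before the rank-1 fit.  The rectified
    tensors have a strictly positive sampling-noise floor, which acts as a
    large near-uniform rank-1 component; left in place it dominates the
    factorization at realistic dimensions and flattens the canonical
    weights, so it is removed before optimizing.

    With ``scale_structures`` (default) each structure's scaling factor is
    multiplied by 1/||C||_F^2, so every structure contributes a normalized
    squared correlation (rho/||C||_F)^2 <= 1 to the objective.  Without
    this, raw rho^2 grows with tensor size and the highest-order structure
    (whose empirical moment tensor is also the noisiest at N << d) drowns
    the reliable lower-order ones.  User scalings multiply on top.
    """
    if density is None:
        density = estimate_covariance_density(blocks, spec, scheme)
    common, distinct = biased_subsample(density, scheme, blocks)
    k = len(blocks)
    dims = [b.n_features for b in blocks]
    s = scheme.n_subsamples
    matrices = [np.zeros((d, s)) for d in dims]
    supports: list[list[np.ndarray]] = []
    converged: list[bool] = []
    seeds = np.random.SeedSequence(scheme.seed + 2).spawn(s)
    for i in range(s):
        idx = [np.sort(np.concatenate([common[j], distinct[i][j]])).astype(int)
               for j in range(k)]
        sub = [b.values[:, idx[j]] for j, b in enumerate(blocks)]
        tensors = {}
        for st in spec.structures:
            t = covariance_tensor([sub[v] for v in st], view_indices=st).entries
            tensors[st] = t - t.mean() if center_tensors else t
        if scale_structures:
            scalings = [a / max(float((tensors[st]**2).sum()), 1e-300)
                        for a, st in zip(spec.scalings, spec.structures)]
            sub_spec = StructureSpec(list(spec.structures), scalings)
        else:
            sub_spec = spec
        problem = GtccaProblem(tensors, [len(ix) for ix in idx], sub_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = gtcca.solve(problem, init=init,
                              seed=np.random.default_rng(seeds[i]),
                              max_iter=max_iter, grad_tol=grad_tol)
        if not sol.converged:
            warnings.warn(f"subsample {i}: GTCCA did not converge; column kept",
                          RuntimeWarning, stacklevel=2)
        for j in range(k):
            matrices[j][idx[j], i] = sol.weights[j]
        supports.append(idx)
        converged.append(sol.converged)
        log.debug("subsample %d: supports %s, %d iterations, objective %.6g",
                  i, [len(ix) for ix in idx], sol.n_iter,
                  sol.objective_trace[-1])
    return CanonicalWeightMatrices(matrices, supports, converged, density)
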