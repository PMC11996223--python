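"""Latent-factor multi-omics simulator with ground-truth signal labels.

Three omics views of 1000 features each are driven by 11 independent
latent factors in fixed feature blocks; a quantitative phenotype is the sum
of a case-dependent subset of those factors plus noise.  Three cases vary
which correlation structures carry phenotype signal:

* case 1 -- phenotype driven by latents 1-7: 4-way, 3-way and pairwise
  phenotype-specific structures are all signal;
* case 2 -- phenotype driven by latent 1 only: only the 4-way structure
  (latent 1 spans all three views) is signal;
* case 3 -- phenotype driven by latents 2-7: 3-way and pairwise structures
  are signal, the 4-way one is not.

Latents 8-11 drive purely inter-omics blocks in every case; they are never
signal and exist to interfere with signal identification.  Three settings
control the factor distribution: ``normal`` (iid standard normal),
``skewed`` (Fleishman cubic transform to a highly right-skewed marginal)
and ``noisy`` (normal factors plus strong extra noise on every omics
feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BLOCKS",
    "VIEW_FACTORS",
    "SimulationDesign",
    "SimulatedDataset",
    "fleishman_coefficients",
    "draw_latent_factors",
    "assemble_dataset",
]

# feature blocks (0-based, half-open) and the latent factor driving each
# block per view; None marks a pure-noise block
BLOCKS: list[tuple[int, int]] = [
    (0, 20), (20, 40), (40, 60), (60, 80), (80, 100),
    (100, 160), (160, 220), (220, 280), (280, 340), (340, 1000),
]
VIEW_FACTORS: list[list[int | None]] = [
    [1, 2, 3, None, 5, 8, 9, 10, None, None],   # omics 1
    [1, 2, None, 4, 6, 8, 9, None, 11, None],   # omics 2
    [1, None, 3, 4, 7, 8, None, 10, 11, None],  # omics 3
]
PHENOTYPE_FACTORS: dict[int, list[int]] = {
    1: [1, 2, 3, 4, 5, 6, 7],
    2: [1],
    3: [2, 3, 4, 5, 6, 7],
}


@dataclass
class SimulationDesign:
    """Full specification of one simulated dataset."""

    case: int = 1
    setting: str = "normal"
    n_samples: int = 100
    n_features: int = 1000
    omics_noise_sd: float = 0.5
    phenotype_noise_sd: float = 1.0
    extra_omics_noise_sd: float = 1.1   # applied only in the "noisy" setting
    skewness: float = 3.5
    excess_kurtosis: float = 22.0
    seed: int = 0
    blocks: list[tuple[int, int]] = field(default_factory=lambda: list(BLOCKS))
    view_factors: list[list[int | None]] = field(
        default_factory=lambda: [list(v) for v in VIEW_FACTORS])

    def __post_init__(self) -> None:
        if self.case not in (1, 2, 3):
            raise ValueError("case must be 1, 2 or 3")
        if self.setting not in ("normal", "skewed", "noisy"):
            raise ValueError("setting must be 'normal', 'skewed' or 'noisy'")
        covered = sorted((a, b) for a, b in self.blocks)
        if covered[0][0] != 0 or covered[-1][1] != self.n_features:
            raise ValueError("blocks must cover the full feature range")
        for (a, b), (c, d) in zip(covered, covered[1:]):
            if b != c:
                raise ValueError("blocks must tile the feature range without overlap")

    @property
    def phenotype_factors(self) -> list[int]:
        return list(PHENOTYPE_FACTORS[self.case])

    @property
    def signal_factors(self) -> set[int]:
        return set(self.phenotype_factors)


@dataclass
class SimulatedDataset:
    omics: list[np.ndarray]          # each n x d
    phenotype: np.ndarray            # n
    signal_labels: list[np.ndarray]  # binary per feature per view
    latent_factors: np.ndarray       # n x 11, for diagnostics
    design: SimulationDesign


def fleishman_coefficients(skewness: float, excess_kurtosis: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the Fleishman cubic a + bZ + cZ^2 + dZ^3
    producing zero mean, unit variance and the target third/fourth moments.

    Solved from the classical moment equations; infeasible pairs (kurtosis
    too low for the requested skewness) raise.
    """
    g1, g2 = float(skewness), float(excess_kurtosis)
    if g1 == 0 and g2 == 0:
        return (0.0, 1.0, 0.0, 0.0)

    def equations(p):
        b, c, d = p
        f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1
        f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - g1
        f3 = 24 * (b * d + c**2 * (1 + b**2 + 28 * b * d)
                   + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)) - g2
        return [f1, f2, f3]

    sol, info, ier, _ = optimize.fsolve(
        equations, x0=[0.9, 0.1 * np.sign(g1) if g1 else 0.0, 0.05],
        full_output=True)
    if ier != 1 or np.max(np.abs(equations(sol))) > 1e-9:
        raise ValueError(
            f"no Fleishman solution for skewness={g1}, excess kurtosis={g2}")
    b, c, d = (float(v) for v in sol)
    return (-c, b, c, d)


def draw_latent_factors(n: int, n_factors: int = 11, setting: str = "normal",
                        seed: int | np.random.Generator = 0,
                        skewness: float = 3.5,
                        excess_kurtosis: float = 22.0) -> np.ndarray:
    """Draw independent latent factors, each ~ mean 0 / variance 1.

    The ``skewed`` setting pushes each factor through the Fleishman cubic;
    ``normal`` and ``noisy`` use standard normal factors (the extra noise of
    the noisy setting is applied to the features, not the factors).
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, n_factors))
    if setting == "skewed":
        a, b, c, d = fleishman_coefficients(skewness, excess_kurtosis)
        z = a + b * z + c * z**2 + d * z**3
    return z


def assemble_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Build the omics matrices, phenotype and signal labels for a design.

    Each feature is its block's latent factor plus Gaussian noise (pure
    Gaussian for noise blocks); the phenotype is the sum of the case's
    factors plus stronger Gaussian noise.
    """
    rng = np.random.default_rng(design.seed)
    n, d = design.n_samples, design.n_features
    latents = draw_latent_factors(
        n, 11, design.setting, rng,
        design.skewness, design.excess_kurtosis)

    omics: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    signal = design.signal_factors
    for factors in design.view_factors:
        x = np.empty((n, d))
        lab = np.zeros(d, dtype=int)
        for (a, b), f in zip(design.blocks, factors):
            width = b - a
            if f is None:
                x[:, a:b] = rng.standard_normal((n, width))
            else:
                x[:, a:b] = (latents[:, f - 1][:, None]
                             + design.omics_noise_sd * rng.standard_normal((n, width)))
                if f in signal:
                    lab[a:b] = 1
        if design.setting == "noisy":
            x = x + design.extra_omics_noise_sd * rng.standard_normal((n, d))
        omics.append(x)
        labels.append(lab)

    pheno = latents[:, [f - 1 for f in design.phenotype_factors]].sum(axis=1)
    pheno = pheno + design.phenotype_noise_sd * rng.standard_normal(n)
    return SimulatedDataset(omics, pheno, labels, latents, design)
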