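"""Higher-order covariance and dense tensor algebra primitives.

Every downstream stage of the pipeline operates on *standardized* feature
matrices (columns centered, scaled to unit population variance) and on
nonnegative higher-order covariance tensors built from them.

The higher-order covariance of k standardized N-vectors is

    rho(z_1, ..., z_k) = | (1/N) sum_i  z_1i * z_2i * ... * z_ki |       (k even)
    rho(z_1, ..., z_k) = (1/(N*k)) sum_j | sum_i z_1i ... |z_ji| ... z_ki |   (k odd)

The odd-k branch replaces one vector at a time by its absolute value and
averages, which prevents the exact cancellation that the naive signed
product statistic suffers for an odd number of views (a symmetric-about-zero
vector z gives sum z^3 = 0 even when the three views are identical).

The order-k covariance tensor over k feature blocks evaluates this scalar
for every combination of one feature column per block; it is computed by
einsum contractions rather than entrywise loops.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedBlock",
    "CovarianceTensor",
    "standardize",
    "higher_order_covariance",
    "covariance_tensor",
    "mode_product",
    "matricize",
    "fold",
    "khatri_rao",
    "read_block",
    "write_block",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class StandardizedBlock:
    """One omics view with centered / unit-population-variance columns.

    ``values`` is N samples x d features.  Constant (zero-variance) columns
    are stored as all-zero and flagged in ``constant_mask`` so downstream
    stages can exclude them from tensors.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.constant_mask is None:
            self.constant_mask = np.zeros(self.values.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class CovarianceTensor:
    """Dense nonnegative covariance tensor over one correlation structure.

    ``view_indices`` records which views (in pipeline order) the tensor's
    modes correspond to.
    """

    entries: np.ndarray
    view_indices: tuple[int, ...]

    @property
    def order(self) -> int:
        return self.entries.ndim

    @property
    def dims(self) -> tuple[int, ...]:
        return self.entries.shape


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

def standardize(
    raw: np.ndarray | pd.DataFrame,
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> StandardizedBlock:
    """Center each column and scale to unit population variance (1/N).

    Population scaling is used so that the self-covariance of a column is
    exactly 1 and the pairwise covariance tensor is an absolute Pearson
    correlation matrix.  Constant columns become all-zero and are flagged.
    """
    if isinstance(raw, pd.DataFrame):
        if feature_ids is None:
            feature_ids = [str(c) for c in raw.columns]
        if sample_ids is None:
            sample_ids = [str(i) for i in raw.index]
        raw = raw.to_numpy()
    values = np.asarray(raw)
    if values.ndim == 1:
        values = values[:, None]
    if not np.issubdtype(values.dtype, np.number):
        # locate the offending column for the error message
        for j in range(values.shape[1]):
            try:
                np.asarray(values[:, j], dtype=float)
            except (TypeError, ValueError):
                name = feature_ids[j] if feature_ids else str(j)
                raise ValueError(f"non-numeric values in column {name!r}")
        values = values.astype(float)
    values = values.astype(float)
    n, d = values.shape
    if n < 2:
        raise ValueError("standardization requires at least 2 samples")
    if np.isnan(values).any():
        raise ValueError("missing values are not supported; impute upstream")

    centered = values - values.mean(axis=0)
    scale = np.sqrt((centered**2).mean(axis=0))
    constant = scale < 1e-12
    safe = np.where(constant, 1.0, scale)
    z = centered / safe
    z[:, constant] = 0.0

    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(d)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return StandardizedBlock(z, list(feature_ids), list(sample_ids), constant)


# --------------------------------------------------------------------------
# Higher-order covariance
# --------------------------------------------------------------------------

def higher_order_covariance(vectors: list[np.ndarray]) -> float:
    """Nonnegative higher-order covariance of k >= 2 standardized N-vectors."""
    k = len(vectors)
    if k < 2:
        raise ValueError("need at least 2 vectors")
    vs = [np.asarray(v, dtype=float).ravel() for v in vectors]
    n = vs[0].size
    if any(v.size != n for v in vs):
        raise ValueError("vectors must share the same length")
    prod = np.ones(n)
    for v in vs:
        prod = prod * v
    if k % 2 == 0:
        return float(abs(prod.mean()))
    # odd k: average over which vector is absolute-valued
    total = 0.0
    for j in range(k):
        p = np.ones(n)
        for i, v in enumerate(vs):
            p = p * (np.abs(v) if i == j else v)
        total += abs(p.mean())
    return float(total / k)


def _signed_mean_tensor(mats: list[np.ndarray]) -> np.ndarray:
    """(1/N) sum_i outer(x_1i, ..., x_ki), via an optimized einsum."""
    n = mats[0].shape[0]
    letters = string.ascii_lowercase
    subs = ",".join(f"z{letters[j]}" for j in range(len(mats)))
    out = "".join(letters[j] for j in range(len(mats)))
    return np.einsum(f"{subs}->{out}", *mats, optimize=True) / n


def covariance_tensor(
    blocks: list[StandardizedBlock | np.ndarray],
    view_indices: tuple[int, ...] | None = None,
) -> CovarianceTensor:
    """Order-k covariance tensor over k standardized blocks.

    Entry (j1, ..., jk) equals ``higher_order_covariance`` of the
    corresponding feature columns: the absolute mean elementwise product for
    even k, and the averaged absolute-value variant for odd k.
    """
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks")
    mats = [b.values if isinstance(b, StandardizedBlock) else np.asarray(b, float)
            for b in blocks]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("blocks must share the same sample count")
    k = len(mats)
    if k % 2 == 0:
        entries = np.abs(_signed_mean_tensor(mats))
    else:
        acc = None
        for j in range(k):
            slot = [np.abs(m) if i == j else m for i, m in enumerate(mats)]
            t = np.abs(_signed_mean_tensor(slot))
            acc = t if acc is None else acc + t
        entries = acc / k
    if view_indices is None:
        view_indices = tuple(range(k))
    return CovarianceTensor(entries, tuple(view_indices))


# --------------------------------------------------------------------------
# Tensor algebra
# --------------------------------------------------------------------------

def _entries(tensor: CovarianceTensor | np.ndarray) -> np.ndarray:
    return tensor.entries if isinstance(tensor, CovarianceTensor) else np.asarray(tensor, float)


def mode_product(tensor: CovarianceTensor | np.ndarray, weight: np.ndarray, mode: int) -> np.ndarray:
    """Contract ``tensor`` with ``weight`` along ``mode`` (order drops by 1)."""
    t = _entries(tensor)
    if not 0 <= mode < t.ndim:
        raise ValueError(f"mode {mode} out of range for order-{t.ndim} tensor")
    w = np.asarray(weight, dtype=float).ravel()
    if w.size != t.shape[mode]:
        raise ValueError("weight length does not match tensor dimension")
    return np.tensordot(t, w, axes=([mode], [0]))


def matricize(tensor: CovarianceTensor | np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization: mode-i fibers become columns.

    Columns are ordered with the lowest remaining mode varying fastest, so
    that for a rank-1 tensor rho*h1∘h2∘...∘hk the mode-1 matricization is
    rho * h1 * (h_k ⊙ ... ⊙ h2)^T with ⊙ the Khatri-Rao product.
    """
    t = _entries(tensor)
    if not 0 <= mode < t.ndim:
        raise ValueError(f"mode {mode} out of range for order-{t.ndim} tensor")
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1, order="F")


def fold(matrix: np.ndarray, mode: int, dims: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`matricize`: rebuild the tensor of shape ``dims``."""
    rest = [d for i, d in enumerate(dims) if i != mode]
    t = np.asarray(matrix, float).reshape([dims[mode]] + rest, order="F")
    return np.moveaxis(t, 0, mode)


def khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of two matrices with equal column counts."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError("column counts must match")
    return (a[:, None, :] * b[None, :, :]).reshape(a.shape[0] * b.shape[0], a.shape[1])


# --------------------------------------------------------------------------
# Delimited matrix I/O
# --------------------------------------------------------------------------

def read_block(path, sep: str | None = None) -> pd.DataFrame:
    """Read a samples x features matrix: first column sample IDs, header row
    feature IDs.  Delimiter inferred from the extension unless given."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        raise ValueError(f"non-numeric columns in {path}: {bad[:5]}")
    return df


def write_block(df: pd.DataFrame, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep)


def validate_aligned(blocks: list[StandardizedBlock]) -> None:
    """All blocks in one analysis must share identical sample IDs in order."""
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError("blocks do not share identical sample IDs in identical order")
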