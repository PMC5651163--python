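"""Dimension reduction of the calibration system.

Two complementary reductions are provided:

* **Very-sparse random projection** (row sketching).  The ``m × n``
  calibration system is multiplied by a random ``k × m`` matrix ``R`` with
  i.i.d. entries from Li's three-point law — ``±sqrt(s)`` each with
  probability ``1/(2s)``, zero otherwise — using ``s = sqrt(m)``, so only a
  ``1/sqrt(m)`` fraction of entries are nonzero and the sketch costs one
  sparse-dense product.  By the Johnson–Lindenstrauss property the reduced
  least-squares problem has nearly the same residual landscape as the full
  one.  The reduction factor is ``lam = k / n >= 1``; ``k = ceil(lam * n)``.
  The ``sqrt(s)`` scale is kept for fidelity to the distribution even
  though it cancels in least squares.

* **PCA channel compression**: the top principal directions of the
  channel × sample matrix of ACS data map ``nc`` physical coils to ``nv``
  virtual coils, shrinking every downstream dimension that carries a
  channel factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .calibration import CalibrationSystem, KernelGeometry
from .data import MultiCoilKSpace
from .exceptions import ParameterError

__all__ = [
    "ProjectionMatrix",
    "ReducedSystem",
    "ChannelCompressor",
    "make_projection",
    "identity_projection",
    "project_system",
    "fit_channel_compressor",
    "apply_channel_compressor",
]


@dataclass
class ProjectionMatrix:
    """Sparse ``k × m`` very-sparse random projection.

    Entries are ``{+scale, 0, -scale}`` with ``P(±) = 1/(2s)`` and
    ``scale = sqrt(s)`` (``= m**0.25`` for the default ``s = sqrt(m)``).
    """

    R: sp.spmatrix
    s: float
    lam: float
    seed: int | None

    @property
    def k(self) -> int:
        return self.R.shape[0]

    @property
    def m(self) -> int:
        return self.R.shape[1]

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.s))


@dataclass
class ReducedSystem:
    """The sketched calibration system ``T_red = S_red @ W``."""

    S_red: np.ndarray
    T_red: np.ndarray
    lam: float
    geometry: KernelGeometry

    @property
    def k(self) -> int:
        return self.S_red.shape[0]


def make_projection(m: int, n: int, lam: float, s: float | None = None,
                    seed: int | None = None) -> ProjectionMatrix:
    """Draw a very-sparse random projection matrix of shape ``(ceil(lam*n), m)``.

    ``lam >= 1`` is required: with ``k < n`` the reduced system would be
    underdetermined.  ``s`` defaults to ``sqrt(m)`` (Li's very-sparse
    choice); ``s = 1`` and ``s = 3`` give the Achlioptas distributions.
    """
    if m < 1:
        raise ParameterError(f"m must be positive, got {m}")
    if lam < 1:
        raise ParameterError(
            f"reduction factor lam={lam} < 1 would make the reduced system "
            "underdetermined (k < n)")
    if s is None:
        s = float(np.sqrt(m))
    if s < 1:
        raise ParameterError(f"sparsity parameter s must be >= 1, got {s}")
    k = int(np.ceil(lam * n))
    rng = np.random.default_rng(seed)
    total = k * m
    # i.i.d. three-point entries == binomial nonzero count + uniform positions
    nnz = rng.binomial(total, 1.0 / s)
    pos = rng.choice(total, size=nnz, replace=False)
    vals = np.sqrt(s) * rng.choice([-1.0, 1.0], size=nnz)
    R = sp.csr_matrix((vals, (pos // m, pos % m)), shape=(k, m))
    return ProjectionMatrix(R=R, s=float(s), lam=float(lam), seed=seed)


def identity_projection(m: int) -> ProjectionMatrix:
    """Test hook: the identity as a 'projection' (k = m, no reduction)."""
    return ProjectionMatrix(R=sp.identity(m, format="csr"), s=1.0, lam=np.nan, seed=None)


def project_system(cal: CalibrationSystem, proj: ProjectionMatrix) -> ReducedSystem:
    """Sketch the calibration system: ``S_red = R @ S``, ``T_red = R @ T``."""
    if proj.m != cal.m:
        raise ParameterError(
            f"projection has m={proj.m} columns but calibration has m={cal.m} rows")
    S_red = proj.R @ cal.S
    T_red = proj.R @ cal.T
    return ReducedSystem(S_red=np.asarray(S_red), T_red=np.asarray(T_red),
                         lam=proj.lam, geometry=cal.geometry)


@dataclass
class ChannelCompressor:
    """PCA map from ``nc`` physical to ``nv`` virtual channels.

    ``matrix`` holds the top-``nv`` principal directions of the channel ×
    sample ACS data matrix as orthonormal columns (complex); applying the
    compressor projects every k-space sample vector onto them.
    """

    matrix: np.ndarray          # (nc, nv), orthonormal columns
    variance_retained: float

    @property
    def nc(self) -> int:
        return self.matrix.shape[0]

    @property
    def nv(self) -> int:
        return self.matrix.shape[1]


def fit_channel_compressor(ks: MultiCoilKSpace, nv: int) -> ChannelCompressor:
    """Fit the compressor on ACS samples (fully sampled, cheap, representative)."""
    if not 1 <= nv <= ks.nc:
        raise ParameterError(f"nv must be in [1, {ks.nc}], got {nv}")
    if ks.acs_range is not None:
        first, last = ks.acs_range
        X = ks.data[:, first:last + 1, :].reshape(ks.nc, -1)
    else:
        X = ks.data[:, ks.mask].reshape(ks.nc, -1)
    # uncentered complex PCA via the economy SVD of the channel x sample matrix
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    var = sv ** 2
    retained = float(var[:nv].sum() / var.sum()) if var.sum() > 0 else 1.0
    return ChannelCompressor(matrix=U[:, :nv], variance_retained=retained)


def apply_channel_compressor(ks: MultiCoilKSpace, cc: ChannelCompressor) -> MultiCoilKSpace:
    """Map k-space to virtual channels: ``data_v = U[:, :nv]^H @ data``."""
    if cc.nc != ks.nc:
        raise ParameterError(f"compressor expects nc={cc.nc}, data has nc={ks.nc}")
    data_v = np.tensordot(cc.matrix.conj().T, ks.data, axes=1)
    return MultiCoilKSpace(data_v, ks.mask.copy(), ks.acs_range, ks.accel)
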