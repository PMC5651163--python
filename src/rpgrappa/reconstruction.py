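"""GRAPPA synthesis and the named end-to-end reconstruction pipelines.

Synthesis fills every missing k-space sample as the ``W``-weighted
combination of its acquired neighbors on the regular sampling lattice,
using the same kernel geometry and column ordering as calibration.
Acquired samples — including the whole ACS block — are kept verbatim
(bitwise), the standard data-consistency choice.

Edge handling: source windows wrap circularly at the grid edges along both
axes (GRAPPA synthesis as a periodic k-space convolution, the convention of
FFT-based implementations).  Calibration itself still uses only fully
interior windows, so edge behavior never influences the fitted weights.

Pipelines compose the stages ``[channel compression] -> calibration ->
[random projection] -> solver -> synthesis -> sum-of-squares combine`` and
are named after the solver and reductions used: ``grappa`` (direct solve on
the full system), ``rp-grappa`` (sketched + direct), ``cgls-grappa`` /
``hgd-grappa`` (iterative, full), ``rp-cgls-grappa`` / ``rp-hgd-grappa``
(sketched + iterative), with a ``cc-`` prefix adding PCA channel
compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import time

import numpy as np

from .calibration import KernelGeometry, assemble_calibration
from .data import MultiCoilKSpace, kspace_to_image, sos_combine
from .exceptions import GeometryError, ParameterError
from .reduction import (apply_channel_compressor, fit_channel_compressor,
                        make_projection, project_system)
from .solvers import SolverConfig, WeightSet, solve_cgls, solve_hgd, solve_pinv

__all__ = ["PipelineConfig", "ReconResult", "synthesize", "coil_combine_sos",
           "reconstruct", "PIPELINES"]

PIPELINES = tuple(
    prefix + base
    for prefix in ("", "cc-")
    for base in ("grappa", "rp-grappa", "cgls-grappa", "rp-cgls-grappa",
                 "hgd-grappa", "rp-hgd-grappa"))


def synthesize(ks: MultiCoilKSpace, weights: WeightSet | np.ndarray,
               geom: KernelGeometry) -> MultiCoilKSpace:
    """Fill missing phase-encode lines of ``ks`` using GRAPPA weights.

    Every missing sample at lattice phase ``t`` (1..A_f-1 above the nearest
    lower acquired lattice row) is computed from the ``d_y`` acquired lines
    around it and ``d_x`` readout taps, for all channels at once.
    """
    W = weights.W if isinstance(weights, WeightSet) else np.asarray(weights)
    if W.shape != (geom.n, geom.l):
        raise GeometryError(f"weights shape {W.shape} != ({geom.n}, {geom.l})")
    if geom.nc != ks.nc:
        raise GeometryError(f"geometry expects nc={geom.nc}, data has nc={ks.nc}")
    A, dy, dx, nc = geom.accel, geom.d_y, geom.d_x, geom.nc
    if A == 1 or not (~ks.mask).any():
        return ks.copy()

    ny, nx = ks.ny, ks.nx
    offset = ks.lattice_offset()
    ctr = (dx - 1) // 2
    xtap = [(np.arange(nx) - ctr + ix) % nx for ix in range(dx)]  # circular taps
    out = ks.data.copy()
    row_acquired = ks.mask.all(axis=1)

    # weight columns regrouped per offset t: Wt[t-1] has shape (n, nc)
    Wt = [W[:, (t - 1)::(A - 1)] if A > 1 else None for t in geom.offsets]

    for y in np.flatnonzero(~row_acquired):
        t = (y - offset) % A
        if t == 0:
            continue  # lattice row; acquired by construction
        y0 = y - t - geom.j0 * A
        src_rows = (y0 + np.arange(dy) * A) % ny         # circular at PE edges
        # Sbig[x, (c, iy, ix)] = data[c, src_rows[iy], (x - ctr + ix) % nx]
        Sbig = np.empty((nx, nc, dy, dx), dtype=ks.data.dtype)
        for iy in range(dy):
            block = ks.data[:, src_rows[iy], :]          # (nc, nx)
            for ix in range(dx):
                Sbig[:, :, iy, ix] = block[:, xtap[ix]].T
        vals = Sbig.reshape(nx, geom.n) @ Wt[t - 1]      # (nx, nc)
        out[:, y, :] = vals.T
    # acquired samples (scattered or full rows) retained verbatim
    out[:, ks.mask] = ks.data[:, ks.mask]
    return MultiCoilKSpace(out, np.ones_like(ks.mask), acs_range=(0, ny - 1), accel=1)


def coil_combine_sos(filled: MultiCoilKSpace) -> np.ndarray:
    """Per-channel inverse DFT followed by root-sum-of-squares combination."""
    return sos_combine(kspace_to_image(filled.data))


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end reconstruction."""

    pipeline: str = "grappa"
    kernel: tuple[int, int] = (4, 5)        # (d_y, d_x)
    lam: float = 2.5                        # RP reduction factor (k / n)
    virtual_channels: int | None = None     # CC target, required for cc-* pipelines
    solver_config: SolverConfig = field(default_factory=SolverConfig)
    rp_seed: int | None = None
    rp_s: float | None = None               # None -> sqrt(m)
    pinv_mode: str = "stable"

    def __post_init__(self) -> None:
        name = self.pipeline.lower().replace("_", "-")
        if name not in PIPELINES:
            raise ParameterError(
                f"unknown pipeline {self.pipeline!r}; choose from {PIPELINES}")
        self.pipeline = name

    @property
    def use_cc(self) -> bool:
        return self.pipeline.startswith("cc-")

    @property
    def use_rp(self) -> bool:
        return "rp-" in self.pipeline

    @property
    def solver(self) -> str:
        if "cgls" in self.pipeline:
            return "cgls"
        if "hgd" in self.pipeline:
            return "hgd"
        return "pinv"


@dataclass
class ReconResult:
    """Output of :func:`reconstruct`: filled k-space, images and diagnostics."""

    filled_kspace: MultiCoilKSpace
    coil_images: np.ndarray
    composite: np.ndarray
    pipeline: str
    weights: WeightSet
    lam: float | None
    condition_number: float | None
    elapsed_s: float
    config: PipelineConfig


def reconstruct(ks: MultiCoilKSpace, config: PipelineConfig) -> ReconResult:
    """Run one named pipeline end to end on undersampled k-space."""
    t0 = time.perf_counter()
    work = ks
    if config.use_cc:
        if config.virtual_channels is None:
            raise ParameterError("cc-* pipelines require virtual_channels")
        cc = fit_channel_compressor(work, config.virtual_channels)
        work = apply_channel_compressor(work, cc)

    geom = KernelGeometry(d_y=config.kernel[0], d_x=config.kernel[1],
                          accel=work.accel, nc=work.nc)
    try:
        cal = assemble_calibration(work, geom)
    except GeometryError as exc:
        raise GeometryError(f"calibration stage: {exc}") from exc

    lam = None
    if config.use_rp:
        lam = config.lam
        proj = make_projection(cal.m, geom.n, lam, s=config.rp_s, seed=config.rp_seed)
        red = project_system(cal, proj)
        S, T = red.S_red, red.T_red
    else:
        S, T = cal.S, cal.T

    if config.solver == "pinv":
        weights = solve_pinv(S, T, mode=config.pinv_mode)
    elif config.solver == "cgls":
        weights = solve_cgls(S, T, config.solver_config)
    else:
        weights = solve_hgd(S, T, config.solver_config)

    filled = synthesize(work, weights, geom)
    coil_images = kspace_to_image(filled.data)
    composite = sos_combine(coil_images)
    elapsed = time.perf_counter() - t0
    return ReconResult(filled_kspace=filled, coil_images=coil_images,
                       composite=composite, pipeline=config.pipeline,
                       weights=weights, lam=lam, condition_number=None,
                       elapsed_s=elapsed, config=config)
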