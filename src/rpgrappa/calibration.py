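"""GRAPPA kernel geometry and calibration-system assembly.

Calibration stacks every kernel placement over the fully sampled ACS block
into an overdetermined linear system ``T = S @ W``: each row of the source
matrix ``S`` holds the ``d_y * d_x * nc`` acquired samples of one placement,
and the matching row of the target matrix ``T`` holds the ``nc * (A_f - 1)``
missing-line samples centrally located within the kernel's phase-encode
span.  A single weight matrix solves all missing offsets jointly.

Conventions (fixed and relied on by synthesis):

* placements iterate row-major — phase-encode outer, readout inner;
* source columns are ordered ``(channel, d_y, d_x)``;
* target columns are ordered ``(channel, offset)`` with offsets
  ``t = 1 .. A_f - 1`` counted from the lower central source line;
* the fitted gap is the one between the two central source lines
  (``j0 = d_y // 2 - 1``), the standard symmetric-interpolation choice;
* readout windows are fully interior (no wrap, no padding).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .data import MultiCoilKSpace
from .exceptions import GeometryError

__all__ = ["KernelGeometry", "CalibrationSystem", "kernel_span", "assemble_calibration"]


@dataclass(frozen=True)
class KernelGeometry:
    """GRAPPA kernel shape: ``d_y`` source lines × ``d_x`` readout taps × all coils.

    ``d_y`` counts *acquired* lines, spaced ``accel`` apart, so the kernel
    spans ``(d_y - 1) * accel + 1`` phase-encode rows.
    """

    d_y: int
    d_x: int
    accel: int
    nc: int

    def __post_init__(self) -> None:
        if self.d_y < 2:
            raise GeometryError(f"d_y must be >= 2, got {self.d_y}")
        if self.d_x < 1 or self.d_x % 2 == 0:
            raise GeometryError(f"d_x must be odd and >= 1, got {self.d_x}")
        if self.accel < 1:
            raise GeometryError(f"accel must be >= 1, got {self.accel}")
        if self.nc < 1:
            raise GeometryError(f"nc must be >= 1, got {self.nc}")

    @property
    def n(self) -> int:
        """Source columns: d_y * d_x * nc."""
        return self.d_y * self.d_x * self.nc

    @property
    def l(self) -> int:
        """Target columns: nc * (accel - 1)."""
        return self.nc * (self.accel - 1)

    @property
    def span(self) -> int:
        """Phase-encode rows covered by the kernel: (d_y - 1) * accel + 1."""
        return kernel_span(self)

    @property
    def j0(self) -> int:
        """Index of the lower central source line (0-based)."""
        return self.d_y // 2 - 1

    @property
    def offsets(self) -> np.ndarray:
        """Missing-line offsets t = 1 .. accel-1 relative to the lower central line."""
        return np.arange(1, self.accel)

    @classmethod
    def parse(cls, text: str, accel: int, nc: int) -> "KernelGeometry":
        """Build from a 'DYxDX' string such as '4x5'."""
        try:
            d_y, d_x = (int(p) for p in text.lower().split("x"))
        except ValueError as exc:
            raise GeometryError(f"cannot parse kernel spec {text!r}") from exc
        return cls(d_y=d_y, d_x=d_x, accel=accel, nc=nc)


def kernel_span(geom: KernelGeometry) -> int:
    """Phase-encode span of the kernel in rows: ``(d_y - 1) * accel + 1``."""
    return (geom.d_y - 1) * geom.accel + 1


@dataclass
class CalibrationSystem:
    """The stacked GRAPPA calibration system ``T = S @ W``."""

    S: np.ndarray            # (m, n) complex
    T: np.ndarray            # (m, l) complex
    geometry: KernelGeometry

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @staticmethod
    def expected_rows(acs_lines: int, nx: int, geom: KernelGeometry) -> int:
        """Closed-form placement count: (acs - span + 1) * (nx - d_x + 1)."""
        return (acs_lines - geom.span + 1) * (nx - geom.d_x + 1)


def assemble_calibration(ks: MultiCoilKSpace, geom: KernelGeometry) -> CalibrationSystem:
    """Collect all kernel repetitions over the ACS into ``S`` and ``T``.

    Raises :class:`GeometryError` if the ACS is shorter than the kernel span
    or the readout narrower than ``d_x``.  Warns when the system is not
    overdetermined (``m < n``), the regime the solvers assume.
    """
    if geom.nc != ks.nc:
        raise GeometryError(f"geometry expects nc={geom.nc}, data has nc={ks.nc}")
    if ks.acs_range is None:
        raise GeometryError("input has no ACS block")
    first, last = ks.acs_range
    acs_lines = last - first + 1
    span = geom.span
    if acs_lines < span:
        raise GeometryError(
            f"ACS of {acs_lines} lines is shorter than the kernel span {span}")
    if ks.nx < geom.d_x:
        raise GeometryError(f"readout width {ks.nx} < kernel taps d_x={geom.d_x}")

    A, dy, dx, nc = geom.accel, geom.d_y, geom.d_x, geom.nc
    ctr = (dx - 1) // 2
    y0s = np.arange(first, last - span + 2)        # placement top rows
    x0s = np.arange(ks.nx - dx + 1)                # placement left taps
    nyp, nxp = len(y0s), len(x0s)

    # S5[c, p, q, iy, ix] = data[c, y0s[p] + iy*A, x0s[q] + ix]
    S5 = np.empty((nc, nyp, nxp, dy, dx), dtype=ks.data.dtype)
    for iy in range(dy):
        rows = y0s + iy * A
        for ix in range(dx):
            S5[:, :, :, iy, ix] = ks.data[:, rows[:, None], x0s[None, :] + ix]
    # rows: placements row-major (pe outer, readout inner); cols: (c, iy, ix)
    S = S5.transpose(1, 2, 0, 3, 4).reshape(nyp * nxp, geom.n)

    if geom.l:
        T4 = np.empty((nc, nyp, nxp, A - 1), dtype=ks.data.dtype)
        for ti, t in enumerate(geom.offsets):
            rows = y0s + geom.j0 * A + t
            T4[:, :, :, ti] = ks.data[:, rows[:, None], x0s[None, :] + ctr]
        T = T4.transpose(1, 2, 0, 3).reshape(nyp * nxp, geom.l)
    else:
        T = np.zeros((nyp * nxp, 0), dtype=ks.data.dtype)

    m = S.shape[0]
    if m < geom.n:
        warnings.warn(
            f"calibration system has m={m} rows < n={geom.n} columns; "
            "the overdetermined regime the solvers assume does not hold",
            stacklevel=2)
    return CalibrationSystem(S=S, T=T, geometry=geom)
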