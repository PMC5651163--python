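"""Multi-coil Cartesian k-space containers and synthetic acquisition generators.

The package works on 2-D Cartesian multi-coil k-space stored as a complex
array of shape ``(nc, ny, nx)`` — channels, phase-encode, readout.  The
phase-encode direction is always array axis 1.  k-space is stored with DC at
the array center (FFT-shifted layout); the forward DFT is unnormalized and
the inverse carries the ``1/N`` factor, matching common MRI practice.

Because the in vivo acquisitions this package targets are not distributable,
a synthetic generator is provided: a Shepp–Logan (or smooth-blob) phantom is
multiplied by simulated coil sensitivity maps and Fourier transformed, with
optional circular complex Gaussian noise.  Retrospective undersampling keeps
a centered, fully sampled autocalibration (ACS) block plus every ``A_f``-th
phase-encode line elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from .exceptions import FormatError, InvalidSpecError

__all__ = [
    "MultiCoilKSpace",
    "PhantomSpec",
    "image_to_kspace",
    "kspace_to_image",
    "sos_combine",
    "generate_phantom_kspace",
    "undersample",
    "make_exact_kernel_kspace",
    "read_container",
    "write_container",
    "export_png",
]


# ---------------------------------------------------------------------------
# Fourier conventions
# ---------------------------------------------------------------------------

def image_to_kspace(img: np.ndarray) -> np.ndarray:
    """Unnormalized forward 2-D DFT over the last two axes, DC at center."""
    return fftshift(fft2(ifftshift(img, axes=(-2, -1)), axes=(-2, -1)), axes=(-2, -1))


def kspace_to_image(ksp: np.ndarray) -> np.ndarray:
    """Inverse 2-D DFT (1/N normalized) over the last two axes, DC at center."""
    return fftshift(ifft2(ifftshift(ksp, axes=(-2, -1)), axes=(-2, -1)), axes=(-2, -1))


def sos_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares composite of per-coil images (channel axis 0)."""
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class MultiCoilKSpace:
    """Complex multi-coil Cartesian k-space with sampling metadata.

    Parameters
    ----------
    data : complex ndarray, shape (nc, ny, nx)
        Channel-stacked k-space; zero at unacquired positions.
    mask : bool ndarray, shape (ny, nx)
        True where a sample was acquired.
    acs_range : (int, int) or None
        Inclusive ``(first, last)`` phase-encode interval of the contiguous
        fully sampled autocalibration block; ``None`` if there is none.
    accel : int
        Nominal acceleration factor ``A_f`` (1 = fully sampled).
    """

    data: np.ndarray
    mask: np.ndarray
    acs_range: tuple[int, int] | None = None
    accel: int = 1

    pe_axis = 1  # fixed convention: phase-encode is axis 1 of (nc, ny, nx)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise InvalidSpecError(f"data must be 3-D (nc, ny, nx); got {self.data.shape}")
        if self.data.shape[0] < 1:
            raise InvalidSpecError("need at least one channel")
        if self.mask.shape != self.data.shape[1:]:
            raise InvalidSpecError(
                f"mask shape {self.mask.shape} != grid shape {self.data.shape[1:]}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.accel < 1:
            raise InvalidSpecError(f"accel must be >= 1, got {self.accel}")
        if self.acs_range is not None:
            first, last = self.acs_range
            if not (0 <= first <= last < self.ny):
                raise InvalidSpecError(f"acs_range {self.acs_range} outside [0, {self.ny})")
            if not self.mask[first:last + 1].all():
                raise InvalidSpecError("mask must be fully true inside acs_range")

    @property
    def nc(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    @property
    def acs_lines(self) -> int:
        if self.acs_range is None:
            return 0
        return self.acs_range[1] - self.acs_range[0] + 1

    def acquired_rows(self) -> np.ndarray:
        """Indices of phase-encode rows that are (fully) acquired."""
        return np.flatnonzero(self.mask.all(axis=1))

    def lattice_offset(self) -> int:
        """Congruence offset (mod accel) of the regularly acquired rows.

        Derived from the mask: the offset class with acquired rows outside
        the ACS block; falls back to the ACS center for accel == 1.
        """
        if self.accel == 1:
            return 0
        rows = self.acquired_rows()
        if self.acs_range is not None:
            first, last = self.acs_range
            outside = rows[(rows < first) | (rows > last)]
        else:
            outside = rows
        if outside.size == 0:  # only an ACS: put the lattice through its center
            return (self.ny // 2) % self.accel
        offs = np.unique(outside % self.accel)
        return int(offs[0])

    def copy(self) -> "MultiCoilKSpace":
        return MultiCoilKSpace(self.data.copy(), self.mask.copy(), self.acs_range, self.accel)


# ---------------------------------------------------------------------------
# Synthetic phantom acquisitions
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Specification of a synthetic multi-coil acquisition.

    ``noise_sigma`` is the standard deviation of circular complex Gaussian
    noise added per k-space sample (real and imaginary parts each get
    ``sigma / sqrt(2)``); it is expressed as a *fraction of the RMS of the
    noiseless k-space* so that one number is meaningful across grid sizes.
    """

    image_size: tuple[int, int] = (256, 256)
    phantom_kind: str = "shepp_logan"          # or "smooth_blobs"
    nc: int = 8
    sensitivity_kind: str = "gaussian_profile"  # or "polynomial"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.image_size
        if ny < 32 or nx < 32:
            raise InvalidSpecError(f"image_size must be at least 32x32, got {self.image_size}")
        if self.nc < 1:
            raise InvalidSpecError("nc must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if self.phantom_kind not in ("shepp_logan", "smooth_blobs"):
            raise InvalidSpecError(f"unknown phantom_kind {self.phantom_kind!r}")
        if self.sensitivity_kind not in ("gaussian_profile", "polynomial", "uniform"):
            raise InvalidSpecError(f"unknown sensitivity_kind {self.sensitivity_kind!r}")


def _phantom_image(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.image_size
    if spec.phantom_kind == "shepp_logan":
        from skimage.data import shepp_logan_phantom
        from skimage.transform import resize
        img = resize(shepp_logan_phantom(), (ny, nx), anti_aliasing=True,
                     preserve_range=True)
    else:  # smooth_blobs: a deterministic sum of Gaussian bumps
        rng = np.random.default_rng(spec.seed + 101)
        yy, xx = np.mgrid[0:ny, 0:nx]
        yy = (yy - ny / 2) / ny
        xx = (xx - nx / 2) / nx
        img = np.zeros((ny, nx))
        for _ in range(6):
            cy, cx = rng.uniform(-0.25, 0.25, size=2)
            w = rng.uniform(0.05, 0.2)
            a = rng.uniform(0.3, 1.0)
            img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w ** 2))
        img /= img.max()
    return img.astype(float)


def _sensitivity_maps(spec: PhantomSpec) -> np.ndarray:
    """Simulated complex coil sensitivities, shape (nc, ny, nx).

    ``gaussian_profile`` places coil centers on an ellipse around the FOV
    with broad Gaussian falloff and a smooth per-coil phase ramp, a standard
    stand-in for array-coil B1- maps.  Sensitivities never vanish jointly:
    the sum-of-squares is bounded away from zero over the whole grid.
    """
    ny, nx = spec.image_size
    nc = spec.nc
    if spec.sensitivity_kind == "uniform":
        return np.ones((nc, ny, nx), dtype=np.complex128)
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy = (yy - ny / 2) / ny   # in [-0.5, 0.5)
    xx = (xx - nx / 2) / nx
    maps = np.empty((nc, ny, nx), dtype=np.complex128)
    if spec.sensitivity_kind == "gaussian_profile":
        angles = 2 * np.pi * np.arange(nc) / nc
        for c, th in enumerate(angles):
            cy, cx = 0.55 * np.sin(th), 0.55 * np.cos(th)
            mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 0.45 ** 2))
            phase = np.exp(1j * (0.7 * np.pi * (np.cos(th) * yy - np.sin(th) * xx)
                                 + 2 * np.pi * c / nc))
            maps[c] = (0.05 + mag) * phase
    else:  # polynomial: smooth low-order complex polynomials in (y, x)
        rng = np.random.default_rng(spec.seed + 577)
        for c in range(nc):
            coef = rng.normal(size=6) + 1j * rng.normal(size=6)
            maps[c] = (1.5 + coef[0] * 0.3 + coef[1] * yy + coef[2] * xx
                       + coef[3] * yy * xx + coef[4] * yy ** 2 + coef[5] * xx ** 2)
    return maps


def generate_phantom_kspace(spec: PhantomSpec) -> tuple[MultiCoilKSpace, np.ndarray]:
    """Simulate a fully sampled multi-coil acquisition.

    Returns
    -------
    ks : MultiCoilKSpace
        Fully sampled k-space, one channel per simulated coil:
        ``DFT(sensitivity_c * phantom)`` plus optional noise.
    reference : ndarray (ny, nx)
        Sum-of-squares composite of the noiseless channel images — the gold
        standard the undersampled reconstructions are scored against.
    """
    img = _phantom_image(spec)
    maps = _sensitivity_maps(spec)
    coil_images = maps * img[None]
    ksp = image_to_kspace(coil_images)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * np.sqrt(np.mean(np.abs(ksp) ** 2))
        noise = rng.normal(size=ksp.shape + (2,), scale=sigma / np.sqrt(2))
        ksp = ksp + noise[..., 0] + 1j * noise[..., 1]
    ny, nx = spec.image_size
    mask = np.ones((ny, nx), dtype=bool)
    ks = MultiCoilKSpace(ksp, mask, acs_range=(0, ny - 1), accel=1)
    reference = sos_combine(coil_images)
    return ks, reference


# ---------------------------------------------------------------------------
# Retrospective undersampling
# ---------------------------------------------------------------------------

def acs_block(ny: int, acs_lines: int) -> tuple[int, int]:
    """Centered inclusive ACS interval: rows ny//2 - acs//2 .. + ceil(acs/2) - 1."""
    first = ny // 2 - acs_lines // 2
    return first, first + acs_lines - 1


def undersample(ks: MultiCoilKSpace, accel: int, acs_lines: int) -> MultiCoilKSpace:
    """Retrospectively undersample along phase-encode.

    Keeps a centered fully sampled ACS block of ``acs_lines`` rows plus every
    ``accel``-th row elsewhere; the lattice offset is chosen so the ACS
    center row lies on the acquired lattice.  All other samples are zeroed.
    """
    if accel < 1:
        raise InvalidSpecError(f"accel must be >= 1, got {accel}")
    if acs_lines > ks.ny:
        raise InvalidSpecError(f"acs_lines={acs_lines} exceeds ny={ks.ny}")
    if not ks.mask.all():
        raise InvalidSpecError("undersample expects fully sampled input")
    if accel == 1:
        return ks.copy()
    ny = ks.ny
    first, last = acs_block(ny, acs_lines)
    offset = (ny // 2) % accel  # ACS center row stays on the lattice
    row_mask = np.zeros(ny, dtype=bool)
    row_mask[offset::accel] = True
    row_mask[first:last + 1] = True
    mask = np.broadcast_to(row_mask[:, None], (ny, ks.nx)).copy()
    data = np.where(mask[None], ks.data, 0.0)
    return MultiCoilKSpace(data, mask, acs_range=(first, last), accel=accel)


# ---------------------------------------------------------------------------
# Exact-kernel fixture
# ---------------------------------------------------------------------------

def make_exact_kernel_kspace(geometry, ny: int, nx: int, seed: int = 0):
    """Fully sampled k-space that satisfies a GRAPPA kernel model *exactly*.

    The data is a sum of ``n = dy*dx*nc`` separable complex-exponential
    modes ``a[c,q] * z_q**y * w_q**x`` with unit-modulus random frequencies
    ``z_q, w_q`` and random channel amplitudes.  For such data the kernel
    relation is fully shift invariant, so a single weight matrix ``W``
    reproduces every missing-line sample from its sources at *every* kernel
    placement, and the calibration source matrix has full column rank —
    which makes ``W`` recoverable to machine precision.  ``W`` is obtained
    by solving the n×n per-mode consistency system.

    Returns
    -------
    ks : MultiCoilKSpace (fully sampled)
    W : ndarray (n, l)
        The embedded weight set (column order matching ``assemble_calibration``).
    """
    from .calibration import KernelGeometry  # local import to avoid a cycle

    geom: KernelGeometry = geometry
    n, l = geom.n, geom.l
    nc, dy, dx, A = geom.nc, geom.d_y, geom.d_x, geom.accel
    if ny % A:
        raise InvalidSpecError(
            f"exact-kernel fixture needs ny divisible by accel ({ny} % {A} != 0) "
            "so the sampling lattice survives periodic wrap-around")
    if n > ny * nx:
        raise InvalidSpecError(f"grid {ny}x{nx} too small for n={n} modes")
    rng = np.random.default_rng(seed)

    # distinct grid-harmonic mode frequencies (exact ny-/nx-th roots of unity,
    # so the kernel relation survives periodic wrap at the grid edges) and
    # random channel amplitudes
    flat = rng.choice(ny * nx, size=n, replace=False)
    zq = np.exp(2j * np.pi * (flat // nx) / ny)
    wq = np.exp(2j * np.pi * (flat % nx) / nx)
    amp = rng.normal(size=(nc, n)) + 1j * rng.normal(size=(nc, n))

    # per-mode source pattern: M[q, (c, iy, ix)] = a[c,q] z_q^(iy*A) w_q^(ix-ctr)
    ctr = (dx - 1) // 2
    iy = np.arange(dy)
    ix = np.arange(dx) - ctr
    zy = zq[:, None] ** (iy[None] * A)                  # (n, dy)
    wx = wq[:, None] ** ix[None]                        # (n, dx)
    pat = zy[:, None, :, None] * wx[:, None, None, :]   # (n, 1, dy, dx)
    M = (amp.T[:, :, None, None] * pat).reshape(n, n)   # columns (c, iy, ix)

    # rhs[q, (c_t, t)] = a[c_t, q] * z_q^(j0*A + t)
    j0 = dy // 2 - 1
    t = np.arange(1, A)
    zt = zq[:, None] ** (j0 * A + t[None])              # (n, A-1)
    rhs = (amp.T[:, :, None] * zt[:, None, :]).reshape(n, l)
    W = np.linalg.solve(M, rhs) if l else np.zeros((n, 0), dtype=complex)

    # data[c, y, x] = sum_q a[c,q] z_q^y w_q^x
    zpow = zq[None, :] ** np.arange(ny)[:, None]        # (ny, n)
    wpow = wq[None, :] ** np.arange(nx)[:, None]        # (nx, n)
    data = np.einsum("cq,yq,xq->cyx", amp, zpow, wpow, optimize=True)
    # normalize to O(1) magnitudes
    data /= np.sqrt(np.mean(np.abs(data) ** 2))
    mask = np.ones((ny, nx), dtype=bool)
    ks = MultiCoilKSpace(data, mask, acs_range=(0, ny - 1), accel=1)
    return ks, W


# ---------------------------------------------------------------------------
# Containers (HDF5 with NPZ fallback)
# ---------------------------------------------------------------------------

def write_container(ks: MultiCoilKSpace, path) -> None:
    """Write a k-space container (HDF5, or NPZ if the suffix is .npz)."""
    path = Path(path)
    first, last = ks.acs_range if ks.acs_range is not None else (-1, -1)
    if path.suffix == ".npz":
        np.savez(path, kspace=ks.data, mask=ks.mask.astype(np.uint8),
                 accel=ks.accel, acs_first=first, acs_last=last)
        return
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ks.data)
        f.create_dataset("mask", data=ks.mask.astype(np.uint8))
        f.attrs["accel"] = ks.accel
        f.attrs["acs_first"] = first
        f.attrs["acs_last"] = last


def read_container(path) -> MultiCoilKSpace:
    """Read a k-space container written by :func:`write_container`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            for name in ("kspace", "mask", "accel", "acs_first", "acs_last"):
                if name not in z:
                    raise FormatError(f"container {path} is missing field '{name}'")
            data, mask = z["kspace"], z["mask"]
            accel = int(z["accel"])
            first, last = int(z["acs_first"]), int(z["acs_last"])
    else:
        import h5py
        with h5py.File(path, "r") as f:
            for name in ("kspace", "mask"):
                if name not in f:
                    raise FormatError(f"container {path} is missing dataset '{name}'")
            for name in ("accel", "acs_first", "acs_last"):
                if name not in f.attrs:
                    raise FormatError(f"container {path} is missing attribute '{name}'")
            data = f["kspace"][...]
            mask = f["mask"][...]
            accel = int(f.attrs["accel"])
            first, last = int(f.attrs["acs_first"]), int(f.attrs["acs_last"])
    if mask.shape != data.shape[1:]:
        raise FormatError(
            f"container {path}: mask shape {mask.shape} does not match kspace grid "
            f"{data.shape[1:]}")
    acs = None if first < 0 else (first, last)
    return MultiCoilKSpace(data, mask.astype(bool), acs_range=acs, accel=accel)


def export_png(image: np.ndarray, path) -> None:
    """Save a magnitude image as an 8-bit grayscale PNG."""
    from PIL import Image
    mag = np.abs(np.asarray(image))
    rng_ = mag.max() - mag.min()
    norm = (mag - mag.min()) / (rng_ if rng_ > 0 else 1.0)
    Image.fromarray((norm * 255).astype(np.uint8)).save(path)
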