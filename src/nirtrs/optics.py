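"""Time-domain diffuse reflectance forward model for a semi-infinite medium.

Units are millimetres and nanoseconds throughout: absorption and reduced
scattering coefficients in 1/mm, source-detector separation in mm, photon
flight times in ns. The speed of light in the medium is ``c0 / n`` with
``c0 = 299.792458 mm/ns``.

The closed-form reflectance is the classic zero-boundary solution of the
time-domain photon diffusion equation::

    R(rho, t) = (4 pi D c)^(-3/2) * z0 * t^(-5/2)
                * exp(-mua c t) * exp(-(rho^2 + z0^2) / (4 D c t))

with isotropic-source depth ``z0 = 1/musp`` and diffusion constant
``D = 1/(3 (mua + musp))`` by default (``D = 1/(3 musp)`` available via
``d_convention="musp"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

C0_MM_PER_NS = 299.792458

__all__ = [
    "C0_MM_PER_NS",
    "OpticalProperties",
    "ProbeGeometry",
    "TimeGrid",
    "TPSF",
    "reflectance",
    "convolve_irf",
    "sample_counts",
    "gaussian_irf",
    "write_tpsf",
    "read_tpsf",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient, 1/mm. Must be positive.
    musp : float
        Reduced scattering coefficient, 1/mm. Must be positive.
    wavelength : float
        Nominal wavelength in nm (metadata; not used by the physics).
    """

    mua: float
    musp: float
    wavelength: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mua) or self.mua <= 0:
            raise ValueError(f"mua must be positive and finite, got {self.mua}")
        if not np.isfinite(self.musp) or self.musp <= 0:
            raise ValueError(f"musp must be positive and finite, got {self.musp}")


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector separation and medium refractive index.

    The default 30 mm separation is the long-channel geometry of a
    two-detector frontal probe; 1.4 is the standard refractive index
    assumed for head tissue.
    """

    rho: float = 30.0
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.refractive_index < 1.0:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )

    @property
    def c(self) -> float:
        """Speed of light in the medium, mm/ns."""
        return C0_MM_PER_NS / self.refractive_index


@dataclass(frozen=True)
class TimeGrid:
    """Uniform TCSPC binning: ``n_bins`` bins of ``bin_width`` ns from ``origin``."""

    bin_width: float = 0.010
    n_bins: int = 4096
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def centers(self) -> np.ndarray:
        """Bin-centre times in ns."""
        return self.origin + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def edges(self) -> np.ndarray:
        return self.origin + np.arange(self.n_bins + 1) * self.bin_width


@dataclass(frozen=True)
class TPSF:
    """A measured (or simulated) photon arrival-time histogram plus its IRF.

    ``counts`` and ``irf_counts`` share one :class:`TimeGrid`. All entries
    must be non-negative; a fittable TPSF has positive total counts.
    """

    grid: TimeGrid
    counts: np.ndarray
    irf_counts: np.ndarray
    wavelength: float
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        irf = np.asarray(self.irf_counts)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "irf_counts", irf)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {counts.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if irf.shape != (self.grid.n_bins,):
            raise ValueError(
                f"irf_counts length {irf.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if np.any(counts < 0):
            raise ValueError("TPSF counts must be non-negative")
        if np.any(irf < 0):
            raise ValueError("IRF counts must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(np.sum(self.counts))


def reflectance(
    geometry: ProbeGeometry,
    props: OpticalProperties,
    grid: TimeGrid | np.ndarray,
    d_convention: str = "mua_musp",
) -> np.ndarray:
    """Time-domain diffuse reflectance at the grid's bin centres.

    Parameters
    ----------
    geometry, props
        Probe geometry and optical properties.
    grid
        A :class:`TimeGrid` (bin centres are used) or an explicit array of
        times in ns; all times must be strictly positive.
    d_convention
        ``"mua_musp"`` uses ``D = 1/(3 (mua + musp))`` (default);
        ``"musp"`` uses the absorption-free ``D = 1/(3 musp)``.

    Returns
    -------
    ndarray
        Strictly positive per-bin photon flux in relative units.
    """
    t = grid.centers if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)
    if np.any(t <= 0):
        raise ValueError("reflectance requires strictly positive times t; "
                         f"min(t) = {t.min()}")
    if d_convention == "mua_musp":
        D = 1.0 / (3.0 * (props.mua + props.musp))
    elif d_convention == "musp":
        D = 1.0 / (3.0 * props.musp)
    else:
        raise ValueError(f"unknown d_convention {d_convention!r}")
    c = geometry.c
    z0 = 1.0 / props.musp
    rho2 = geometry.rho**2
    # evaluate in log space: the Gaussian term underflows at early t
    log_r = (
        -1.5 * np.log(4.0 * np.pi * D * c)
        + np.log(z0)
        - 2.5 * np.log(t)
        - props.mua * c * t
        - (rho2 + z0**2) / (4.0 * D * c * t)
    )
    return np.exp(log_r)


def convolve_irf(model_curve: np.ndarray, irf: np.ndarray) -> np.ndarray:
    """Causal discrete convolution of a model curve with the IRF, truncated
    to the grid length.

    Both arrays must live on the same grid (same length). The output is
    ``(model * irf)[:n]`` and is linear in both arguments.
    """
    model_curve = np.asarray(model_curve, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if model_curve.ndim != 1 or irf.ndim != 1:
        raise ValueError("convolve_irf expects 1-D arrays")
    if model_curve.shape != irf.shape:
        raise ValueError(
            f"grid mismatch: model has {model_curve.shape[0]} bins, "
            f"irf has {irf.shape[0]} bins"
        )
    if irf.sum() <= 0:
        raise ValueError("IRF must have positive total mass")
    n = model_curve.shape[0]
    if n >= 256:
        from scipy.signal import fftconvolve

        out = fftconvolve(model_curve, irf)[:n]
        return np.maximum(out, 0.0)
    return np.convolve(model_curve, irf)[:n]


def sample_counts(
    expected: np.ndarray,
    total_photons: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Poisson photon-count sampling at a fixed total budget.

    ``expected`` is scaled to sum to ``total_photons`` and each bin is
    drawn independently from a Poisson distribution. The same seed yields
    an identical histogram.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    if total_photons < 0:
        raise ValueError(f"total_photons must be >= 0, got {total_photons}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s = expected.sum()
    if s == 0 or total_photons == 0:
        return np.zeros_like(expected, dtype=np.int64)
    lam = expected * (total_photons / s)
    return rng.poisson(lam).astype(np.int64)


def gaussian_irf(
    grid: TimeGrid,
    fwhm_ps: float = 150.0,
    t0_ns: float = 0.3,
    tail_fraction: float = 0.05,
    tail_tau_ns: float = 0.2,
) -> np.ndarray:
    """Simulated instrument response: a Gaussian of given FWHM centred at
    ``t0_ns`` plus a small exponential tail, amplitude-normalised to unit sum.
    """
    t = grid.centers
    sigma = fwhm_ps * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    core = np.exp(-0.5 * ((t - t0_ns) / sigma) ** 2)
    tail = np.where(t >= t0_ns, np.exp(-(t - t0_ns) / tail_tau_ns), 0.0)
    irf = core + tail_fraction * tail
    return irf / irf.sum()


# --- TPSF file format -------------------------------------------------------
#
# Tab-separated, three columns `time_ns  counts  irf_counts`, one header line:
#   # wavelength_nm=763 rho_mm=30 bin_ps=10 origin_ns=0 n=1.4
# Counts are integers, so write-then-read is bit-exact.

_HEADER_RE = re.compile(
    r"#\s*wavelength_nm=(?P<wl>\S+)\s+rho_mm=(?P<rho>\S+)\s+"
    r"bin_ps=(?P<bin>\S+)\s+origin_ns=(?P<origin>\S+)\s+n=(?P<n>\S+)"
)


def write_tpsf(path: str | Path, tpsf: TPSF) -> None:
    """Write a TPSF (counts + IRF) to a tab-separated text file."""
    path = Path(path)
    t = tpsf.grid.centers
    with path.open("w") as fh:
        fh.write(
            f"# wavelength_nm={tpsf.wavelength:g} rho_mm={tpsf.geometry.rho:g} "
            f"bin_ps={tpsf.grid.bin_width * 1e3:g} origin_ns={tpsf.grid.origin:g} "
            f"n={tpsf.geometry.refractive_index:g}\n"
        )
        fh.write("time_ns\tcounts\tirf_counts\n")
        for ti, ci, ii in zip(t, tpsf.counts, tpsf.irf_counts):
            fh.write(f"{ti:.6f}\t{int(ci)}\t{int(ii)}\n")


def read_tpsf(path: str | Path) -> TPSF:
    """Read a TPSF file written by :func:`write_tpsf`.

    Malformed or negative rows are rejected with their line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header)
        if m is None:
            raise ValueError(f"{path}: line 1: missing or malformed TPSF header")
        colnames = fh.readline().strip().split("\t")
        if colnames != ["time_ns", "counts", "irf_counts"]:
            raise ValueError(f"{path}: line 2: unexpected column header {colnames}")
        counts: list[int] = []
        irf: list[int] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            try:
                ci, ii = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer count") from exc
            if ci < 0 or ii < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            counts.append(ci)
            irf.append(ii)
    grid = TimeGrid(
        bin_width=float(m["bin"]) * 1e-3,
        n_bins=len(counts),
        origin=float(m["origin"]),
    )
    geometry = ProbeGeometry(rho=float(m["rho"]), refractive_index=float(m["n"]))
    return TPSF(
        grid=grid,
        counts=np.array(counts, dtype=np.int64),
        irf_counts=np.array(irf, dtype=np.int64),
        wavelength=float(m["wl"]),
        geometry=geometry,
    )
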