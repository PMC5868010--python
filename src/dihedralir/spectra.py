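"""FTIR and absorptive 2D IR spectra from solved exciton systems.

FTIR places a stick of weight |mu01_k|^2 at each one-exciton eigenfrequency.
The absorptive 2D spectrum is a sum-over-states: positive (nu = 0-1) diagonal
peaks at (w_k, w_k) with weight |mu01_k|^4 and negative (nu = 1-2) sequence-
band peaks at (pump w_k, probe w_m - w_k) with weight |mu01_k|^2 |mu12_km|^2.
Lineshapes are Lorentzian or Gaussian; the 2D lineshape is the product of the
pump and probe 1D profiles.  Diagonal disorder is handled by averaging
independent realizations with Gaussian-perturbed site frequencies.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import numpy as np

from .exciton import ExcitonSystem
from .geometry import PeptideModel

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Spectrum2D",
    "DiagonalSlice",
    "LineshapeParams",
    "default_grid",
    "ftir",
    "absorptive_2d",
    "diagonal_slice",
    "disorder_average",
]

#: Default frequency grid: 1540-1700 cm^-1 at 0.5 cm^-1 spacing.
DEFAULT_GRID = (1540.0, 1700.0, 0.5)

#: Sticks this many times weaker than the strongest are dropped from the 2D
#: convolution (pure speed guard; far below lineshape quadrature error).
_STICK_CULL = 1e-10


def default_grid(lo: float = DEFAULT_GRID[0], hi: float = DEFAULT_GRID[1],
                 step: float = DEFAULT_GRID[2]) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class LineshapeParams:
    """Lineshape and disorder settings.

    ``fwhm`` is the homogeneous full width at half maximum (cm^-1);
    ``disorder_sigma`` the standard deviation of Gaussian diagonal (site
    frequency) disorder; ``n_realizations`` the number of disorder draws to
    average; ``seed`` makes the averaging reproducible.
    """

    profile: str = "lorentzian"
    fwhm: float = 12.0
    disorder_sigma: float = 0.0
    n_realizations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.profile not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _profile(grid: np.ndarray, center: float, params: LineshapeParams) -> np.ndarray:
    """Unit-area 1D lineshape evaluated on ``grid``."""
    x = grid - center
    if params.profile == "lorentzian":
        g = params.fwhm / 2.0
        return (g / np.pi) / (x * x + g * g)
    sigma = params.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly increasing frequency grid (cm^-1)."""

    grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid/intensity shape mismatch")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for w, y in zip(self.grid, self.intensity):
                fh.write(f"{w:.6f}\t{y:.8e}\n")

    @classmethod
    def load(cls, path) -> "Spectrum":
        data = np.loadtxt(path)
        return cls(grid=data[:, 0], intensity=data[:, 1])


@dataclass
class Spectrum2D:
    """A signed absorptive 2D spectrum, ``z[i, j]`` at (pump[i], probe[j])."""

    pump: np.ndarray
    probe: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.pump = np.asarray(self.pump, float)
        self.probe = np.asarray(self.probe, float)
        self.z = np.asarray(self.z, float)
        if np.any(np.diff(self.pump) <= 0) or np.any(np.diff(self.probe) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.z.shape != (len(self.pump), len(self.probe)):
            raise ValueError("intensity matrix shape mismatch")

    def save(self, path) -> None:
        """Delimited matrix: header row = probe grid, first column = pump."""
        with open(path, "w") as fh:
            fh.write("pump\\probe\t" + "\t".join(f"{w:.6f}" for w in self.probe) + "\n")
            for i, p in enumerate(self.pump):
                row = "\t".join(f"{v:.8e}" for v in self.z[i])
                fh.write(f"{p:.6f}\t{row}\n")

    @classmethod
    def load(cls, path) -> "Spectrum2D":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        probe = np.array([float(x) for x in lines[0].split("\t")[1:]])
        pump, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            pump.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        return cls(pump=np.array(pump), probe=probe, z=np.array(rows))


@dataclass
class DiagonalSlice:
    """A cut through a 2D spectrum, reported against the pump axis.

    ``band`` is "fundamental" (probe = pump) or "sequence"
    (probe = pump - anharmonic offset); sequence-band slices are signed
    (negative-going) until explicitly negated downstream.
    """

    grid: np.ndarray
    intensity: np.ndarray
    band: str

    def __post_init__(self):
        if self.band not in ("fundamental", "sequence"):
            raise ValueError(f"unknown band {self.band!r}")
        self.grid = np.asarray(self.grid, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid/intensity shape mismatch")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# band={self.band}\n")
            for w, y in zip(self.grid, self.intensity):
                fh.write(f"{w:.6f}\t{y:.8e}\n")

    @classmethod
    def load(cls, path) -> "DiagonalSlice":
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("# band="):
                raise ValueError("missing band header in slice file")
            band = first.split("=", 1)[1]
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        return cls(grid=data[:, 0], intensity=data[:, 1], band=band)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def ftir(system: ExcitonSystem, lines: LineshapeParams = LineshapeParams(),
         grid: np.ndarray = None) -> Spectrum:
    """Linear absorption: |mu01_k|^2 sticks convolved with the lineshape."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    weights = system.mu01_sq()
    y = np.zeros_like(grid)
    dropped = 0
    for w, a in zip(system.e1, weights):
        if not (grid[0] <= w <= grid[-1]):
            dropped += 1
            continue
        y += a * _profile(grid, w, lines)
    if dropped:
        logger.warning("%d FTIR sticks outside the frequency grid dropped",
                       dropped)
    return Spectrum(grid=grid, intensity=y)


def absorptive_2d(system: ExcitonSystem,
                  lines: LineshapeParams = LineshapeParams(),
                  pump_grid: np.ndarray = None,
                  probe_grid: np.ndarray = None) -> Spectrum2D:
    """Sum-over-states absorptive 2D spectrum (see module docstring)."""
    if system.H2.size == 0:
        raise ValueError("system was solved without the two-exciton manifold")
    if pump_grid is None:
        pump_grid = default_grid()
    if probe_grid is None:
        probe_grid = default_grid()
    pump_grid = np.asarray(pump_grid, float)
    probe_grid = np.asarray(probe_grid, float)

    w01sq = system.mu01_sq()
    w12sq = system.mu12_sq()
    sticks = []  # (pump, probe, signed weight)
    for k, wk in enumerate(system.e1):
        # ground-state bleach + stimulated emission: two pathways
        sticks.append((wk, wk, 2.0 * w01sq[k] ** 2))
        for m, wm in enumerate(system.e2):
            wgt = w01sq[k] * w12sq[k, m]
            sticks.append((wk, wm - wk, -wgt))
    wmax = max(abs(s[2]) for s in sticks)
    z = np.zeros((len(pump_grid), len(probe_grid)))
    for wp, wr, a in sticks:
        if abs(a) < _STICK_CULL * wmax:
            continue
        z += a * np.outer(_profile(pump_grid, wp, lines),
                          _profile(probe_grid, wr, lines))
    return Spectrum2D(pump=pump_grid, probe=probe_grid, z=z)


def diagonal_slice(spec: Spectrum2D, band: str,
                   anharmonicity: float = 16.0) -> DiagonalSlice:
    """Cut along probe = pump (fundamental) or probe = pump - Delta
    (sequence), linearly interpolated along the probe axis and reported
    against the pump axis.  Pump points whose track leaves the probe grid
    are dropped; an empty track is an error."""
    if band == "fundamental":
        track = spec.pump
    elif band == "sequence":
        track = spec.pump - anharmonicity
    else:
        raise ValueError(f"unknown band {band!r}")
    inside = (track >= spec.probe[0]) & (track <= spec.probe[-1])
    if not np.any(inside):
        raise ValueError(f"{band} band track lies entirely outside the "
                         "probe grid")
    pump = spec.pump[inside]
    vals = np.empty(len(pump))
    for i, (p, t) in enumerate(zip(np.flatnonzero(inside), track[inside])):
        vals[i] = np.interp(t, spec.probe, spec.z[p])
    return DiagonalSlice(grid=pump, intensity=vals, band=band)


def disorder_average(model: PeptideModel, lines: LineshapeParams,
                     pipeline) -> Spectrum2D:
    """Average 2D spectra over Gaussian diagonal-disorder realizations.

    ``pipeline`` maps a PeptideModel (with perturbed site frequencies) to a
    Spectrum2D; it is invoked ``lines.n_realizations`` times with
    independent zero-mean Gaussian site-frequency perturbations of width
    ``lines.disorder_sigma``.  Identical seed, identical output.
    """
    rng = np.random.default_rng(lines.seed)
    acc = None
    for _ in range(lines.n_realizations):
        if lines.disorder_sigma > 0:
            delta = rng.normal(0.0, lines.disorder_sigma, model.n_sites)
        else:
            delta = np.zeros(model.n_sites)
        m = model.with_site_frequencies(model.site_frequencies + delta)
        spec = pipeline(m)
        if acc is None:
            acc = spec.z.copy()
            pump, probe = spec.pump, spec.probe
        else:
            if spec.z.shape != acc.shape:
                raise ValueError("pipeline returned inconsistent grids")
            acc += spec.z
    return Spectrum2D(pump=pump, probe=probe, z=acc / lines.n_realizations)
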