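"""Monte-Carlo proximity FRET in a two-dimensional membrane.

Fluorophores confined to a membrane undergo FRET even without binding,
simply because random neighbours come within a Forster radius of a donor.
With finite-size fluorophores (a minimum approach distance) this background
has no closed form, so it is simulated: acceptors are placed as a Poisson
point process around a central donor, excluding a hard core, and the donor
quenching is computed from the parallel-pathway kinetic scheme

    E = S / (1 + S),   S = sum_i (R0 / r_i)^6,

where the sum runs over all acceptors in the simulation disc.  Averaging
over many acceptor configurations at each density yields a lookup table of
proximity FRET vs acceptor density, used by the fitting stage as a fixed,
density-dependent background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ExtrapolationError

__all__ = [
    "ProximityConfig",
    "ProximityTable",
    "efficiency_from_distances",
    "simulate_proximity",
    "proximity_at",
]

#: Conversion from receptors/um^2 to receptors/A^2.
_PER_UM2_TO_PER_A2 = 1.0e-8


def _default_density_grid() -> np.ndarray:
    return np.linspace(0.0, 8000.0, 41)


@dataclass(frozen=True)
class ProximityConfig:
    """Geometry and sampling parameters of the proximity simulation.

    Parameters
    ----------
    forster_radius : float
        Forster radius of the dye pair, Angstrom.
    exclusion_radius : float
        Minimum donor-acceptor approach (fluorophore hard core), Angstrom.
    sim_disc_radius : float
        Neighbourhood cutoff around the donor, Angstrom; must be at least
        5 R0 so the neglected tail of the r^-6 sum is negligible.
    density_grid : ndarray
        Acceptor densities to tabulate, receptors/um^2, starting at 0.
    n_realizations : int
        Monte-Carlo repeats per density.
    seed : int
        Root seed; per-density streams are spawned deterministically.
    """

    forster_radius: float = 54.5
    exclusion_radius: float = 10.0
    sim_disc_radius: float = 545.0
    density_grid: np.ndarray = field(default_factory=_default_density_grid)
    n_realizations: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise ValueError("Forster radius must be positive")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion radius must be nonnegative")
        if self.sim_disc_radius < 5 * self.forster_radius:
            raise ValueError("simulation disc must extend to at least 5 Forster radii")
        grid = np.asarray(self.density_grid, dtype=float)
        if grid.size == 0 or grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
            raise ValueError("density grid must start at 0 and increase strictly")
        if np.any(grid < 0):
            raise ValueError("densities must be nonnegative")
        object.__setattr__(self, "density_grid", grid)
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")


@dataclass(frozen=True)
class ProximityTable:
    """Tabulated proximity FRET vs acceptor density with Monte-Carlo errors."""

    densities: np.ndarray
    efficiencies: np.ndarray
    stderr: np.ndarray
    config: ProximityConfig | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        e = np.asarray(self.efficiencies, dtype=float)
        s = np.asarray(self.stderr, dtype=float)
        if not (d.shape == e.shape == s.shape):
            raise ValueError("densities, efficiencies and stderr must align")
        if np.any((e < 0) | (e >= 1)):
            raise ValueError("efficiencies must lie in [0, 1)")
        object.__setattr__(self, "densities", d)
        object.__setattr__(self, "efficiencies", e)
        object.__setattr__(self, "stderr", s)

    @property
    def max_density(self) -> float:
        return float(self.densities[-1])


def efficiency_from_distances(distances, forster_radius: float) -> float:
    """Donor quenching by acceptors at the given distances (Angstrom).

    Parallel-pathway combination ``E = S/(1+S)`` with
    ``S = sum (R0/r)^6``; reduces to the pairwise distance law for a single
    acceptor.  Exposed as a deterministic hook for testing the combiner.
    """
    r = np.atleast_1d(np.asarray(distances, dtype=float))
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    s = np.sum((forster_radius / r) ** 6)
    return float(s / (1.0 + s))


def simulate_proximity(config: ProximityConfig = ProximityConfig()) -> ProximityTable:
    """Monte-Carlo proximity-FRET table over the configured density grid.

    For each density the acceptor count in the annulus between the
    exclusion radius and the simulation disc is Poisson with mean
    ``rho * area`` (hard-core rejection of a uniform disc process is
    equivalent to Poisson sampling on the annulus); positions are uniform
    in area.  The mean of ``S/(1+S)`` over ``n_realizations`` independent
    configurations is tabulated together with its standard error.
    """
    r0 = config.forster_radius
    r_in2 = config.exclusion_radius**2
    r_out2 = config.sim_disc_radius**2
    area = np.pi * (r_out2 - r_in2)
    n_real = config.n_realizations

    streams = np.random.SeedSequence(config.seed).spawn(len(config.density_grid))
    eff = np.zeros_like(config.density_grid)
    sem = np.zeros_like(config.density_grid)
    for i, (rho, ss) in enumerate(zip(config.density_grid, streams)):
        lam = rho * _PER_UM2_TO_PER_A2 * area
        if lam == 0.0:
            continue
        rng = np.random.default_rng(ss)
        counts = rng.poisson(lam, size=n_real)
        total = int(counts.sum())
        # uniform in area within the annulus
        r2 = rng.uniform(r_in2, r_out2, size=total)
        s6 = (r0 * r0 / r2) ** 3
        owner = np.repeat(np.arange(n_real), counts)
        s = np.bincount(owner, weights=s6, minlength=n_real)
        e = s / (1.0 + s)
        eff[i] = e.mean()
        sem[i] = e.std(ddof=1) / np.sqrt(n_real)
    return ProximityTable(config.density_grid.copy(), eff, sem, config)


def proximity_at(table: ProximityTable, density) -> float:
    """Proximity FRET at an acceptor density, by linear interpolation.

    Exact at grid nodes; raises :class:`ExtrapolationError` outside
    ``[0, max grid density]``.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d < 0) or np.any(d > table.max_density):
        raise ExtrapolationError(
            f"acceptor density outside tabulated range [0, {table.max_density:g}] "
            "receptors/um^2; regenerate the proximity table with a larger grid"
        )
    out = np.interp(d, table.densities, table.efficiencies)
    return float(out) if out.ndim == 0 else out
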