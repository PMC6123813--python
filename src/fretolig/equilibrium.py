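"""Forward model for FRET in a monomer/n-mer membrane equilibrium.

The measurable FRET efficiency in a membrane region is modelled as the sum
of two contributions: *oligomer FRET* from donors and acceptors bound in the
same n-mer, and *proximity FRET* from fluorophores that happen to be close
in the crowded two-dimensional membrane without interacting.  This module
implements the deterministic part of that model:

* the distance dependence of the pairwise ("intrinsic") FRET efficiency,
  ``E~ = 1 / (1 + (d/R0)^6)``;
* the mass-action partition of a total surface density ``[T]`` into free
  monomers ``[m]`` and n-mers, ``[T] = [m] + n K [m]^n``;
* the donor-averaged oligomer FRET efficiency for a binomially labelled
  n-mer (kinetic-theory form), and its combination with a proximity-FRET
  background into the apparent efficiency;
* the standard-state free energy of dissociation, ``dG = R T ln Kdiss``
  with the standard state at 1 receptor per nm^2.

All surface densities are in receptors/um^2; distances in Angstrom; free
energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import comb

from .errors import UndefinedMeasurementError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_STATE_KDISS",
    "DEFAULT_FORSTER_RADIUS",
    "OligomerModel",
    "EquilibriumState",
    "LabeledPopulation",
    "ThermoContext",
    "intrinsic_fret_from_distance",
    "solve_monomer",
    "monomer_concentration",
    "oligomer_fret",
    "oligomer_fret_sum",
    "apparent_fret",
    "delta_g",
    "assoc_const_for_fraction",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872041e-3

#: Standard-state dissociation constant, 1 receptor per nm^2, in receptors/um^2.
STANDARD_STATE_KDISS = 1.0e6

#: Forster radius of the mTurquoise/eYFP pair, Angstrom.
DEFAULT_FORSTER_RADIUS = 54.5

# Guard band for the intrinsic FRET in kinetic-theory sums; avoids division
# blow-ups in the (1 + (n-k-1) E~) denominators at the open-interval edges.
_E_TILDE_MIN = 1e-6
_E_TILDE_MAX = 1.0 - 1e-6


def intrinsic_fret_from_distance(d: float, r0: float = DEFAULT_FORSTER_RADIUS) -> float:
    """Pairwise FRET efficiency at donor-acceptor separation ``d``.

    ``E~ = 1 / (1 + (d/R0)^6)`` where ``R0`` is the Forster radius of the
    dye pair.  Strictly decreasing in ``d``; equals 1/2 at ``d = R0``.

    Parameters
    ----------
    d : float
        Fluorophore separation, Angstrom (``>= 0``).
    r0 : float
        Forster radius, Angstrom (``> 0``).
    """
    if r0 <= 0:
        raise ValueError(f"Forster radius must be positive, got {r0!r}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = 1.0 / (1.0 + (d / r0) ** 6)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OligomerModel:
    """A monomer/n-mer association hypothesis.

    Parameters
    ----------
    n : int
        Oligomer order (2 = dimer, >2 = cluster).
    intrinsic_fret : float
        Pairwise FRET efficiency ``E~`` within the oligomer, in (0, 1).
    assoc_const : float
        Two-dimensional association constant ``K`` of the monomer <-> n-mer
        equilibrium, units ``(um^2/receptor)^(n-1)``.  ``K = 0`` means no
        specific association.
    forster_radius : float
        Forster radius of the dye pair, Angstrom.
    fluor_distance : float, optional
        Fluorophore separation within the oligomer.  If given, it must be
        consistent with ``intrinsic_fret`` under the distance law.
    """

    n: int
    intrinsic_fret: float
    assoc_const: float
    forster_radius: float = DEFAULT_FORSTER_RADIUS
    fluor_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"oligomer order must be >= 2, got {self.n}")
        if not 0.0 < self.intrinsic_fret < 1.0:
            raise ValueError("intrinsic_fret must lie in the open interval (0, 1)")
        if self.assoc_const < 0:
            raise ValueError("association constant must be nonnegative")
        if self.forster_radius <= 0:
            raise ValueError("Forster radius must be positive")
        if self.fluor_distance is not None:
            implied = intrinsic_fret_from_distance(self.fluor_distance, self.forster_radius)
            if abs(implied - self.intrinsic_fret) > 1e-12:
                raise ValueError(
                    "fluor_distance is inconsistent with intrinsic_fret: "
                    f"distance {self.fluor_distance} A implies E~ = {implied}, "
                    f"got {self.intrinsic_fret}"
                )

    @property
    def kdiss(self) -> float:
        """Dissociation constant ``1/K``, units ``(receptors/um^2)^(n-1)``."""
        if self.assoc_const == 0:
            return np.inf
        return 1.0 / self.assoc_const

    @classmethod
    def from_distance(
        cls,
        n: int,
        fluor_distance: float,
        assoc_const: float,
        forster_radius: float = DEFAULT_FORSTER_RADIUS,
    ) -> "OligomerModel":
        """Build a model with ``E~`` derived from the fluorophore separation."""
        e = intrinsic_fret_from_distance(fluor_distance, forster_radius)
        return cls(n, e, assoc_const, forster_radius, fluor_distance)


@dataclass(frozen=True)
class EquilibriumState:
    """Partition of a total surface density between monomers and n-mers."""

    total_conc: float
    monomer_conc: float
    oligomer_conc: float
    oligo_fraction: float


@dataclass(frozen=True)
class LabeledPopulation:
    """Donor/acceptor composition of the labelled receptor population."""

    donor_conc: float
    acceptor_conc: float

    def __post_init__(self) -> None:
        if self.donor_conc < 0 or self.acceptor_conc < 0:
            raise ValueError("concentrations must be nonnegative")

    @property
    def total_conc(self) -> float:
        return self.donor_conc + self.acceptor_conc

    @property
    def donor_fraction(self) -> float:
        t = self.total_conc
        return self.donor_conc / t if t > 0 else 0.0

    @property
    def acceptor_fraction(self) -> float:
        t = self.total_conc
        return self.acceptor_conc / t if t > 0 else 0.0


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic constants for free-energy reporting."""

    gas_const: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15
    std_state_kdiss: float = STANDARD_STATE_KDISS


def monomer_concentration(total_conc, n: int, assoc_const: float):
    """Free-monomer density solving ``m + n K m^n = [T]``, vectorised.

    The left side is strictly increasing in ``m`` on ``[0, [T]]`` so the
    root is unique; it is located by bisection to ~1e-24 relative accuracy,
    far tighter than any quantity derived from it.
    """
    total = np.asarray(total_conc, dtype=float)
    if np.any(total < 0):
        raise ValueError("total concentration must be nonnegative")
    if assoc_const < 0:
        raise ValueError("association constant must be nonnegative")
    if assoc_const == 0:
        out = total.copy()
        return float(out) if out.ndim == 0 else out
    lo = np.zeros_like(total)
    hi = total.copy()
    nk = n * assoc_const
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        high = mid + nk * mid**n > total
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    out = 0.5 * (lo + hi)
    return float(out) if out.ndim == 0 else out


def solve_monomer(total_conc: float, model: OligomerModel) -> EquilibriumState:
    """Solve the mass-action equilibrium at total density ``[T]``.

    Imposes conservation ``[T] = [m] + n K [m]^n`` and returns the monomer
    density, oligomer density ``mu = K [m]^n`` and protomer oligomeric
    fraction ``f = n mu / [T]``.
    """
    m = monomer_concentration(total_conc, model.n, model.assoc_const)
    mu = model.assoc_const * m**model.n
    f = model.n * mu / total_conc if total_conc > 0 else 0.0
    return EquilibriumState(
        total_conc=float(total_conc),
        monomer_conc=float(m),
        oligomer_conc=float(mu),
        oligo_fraction=float(min(max(f, 0.0), 1.0)),
    )


def _pair_weights(n: int, e_tilde) -> np.ndarray:
    """Kinetic-theory donor weights ``k (n-k) E~ / (1 + (n-k-1) E~)``.

    ``e_tilde`` may be a scalar or an array of shape (m,); the result has
    shape (n-1,) or (m, n-1).
    """
    k = np.arange(1, n)
    e = np.clip(np.asarray(e_tilde, dtype=float), _E_TILDE_MIN, _E_TILDE_MAX)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)[:, None]
    w = k * (n - k) * e / (1.0 + (n - k - 1) * e)
    return w[0] if scalar else w


def _binomial_basis(n: int, x_d, x_a) -> np.ndarray:
    """Binomial labelling terms ``C(n,k) x_D^k x_A^(n-k)``, k = 1..n-1.

    ``x_d``/``x_a`` arrays of shape (N,) give an (N, n-1) matrix.
    """
    k = np.arange(1, n)
    x_d = np.asarray(x_d, dtype=float)[..., None]
    x_a = np.asarray(x_a, dtype=float)[..., None]
    return comb(n, k) * x_d**k * x_a ** (n - k)


def oligomer_fret_sum(n: int, e_tilde: float, x_d, x_a):
    """Binomial sum ``E = sum_k k(n-k)E~/(1+(n-k-1)E~) C(n,k) x_D^k x_A^(n-k)``.

    This is the donor-side FRET sum of a fully oligomeric, binomially
    labelled population; the measurable oligomer FRET is
    ``E_oligo = f_oligo / (n x_D) * E``.
    """
    b = _binomial_basis(n, x_d, x_a)
    w = _pair_weights(n, float(e_tilde))
    out = b @ w
    return float(out) if np.ndim(out) == 0 else out


def oligomer_fret(model: OligomerModel, pop: LabeledPopulation, eq: EquilibriumState) -> float:
    """Donor-averaged FRET efficiency due to specific association.

    Evaluates ``E_oligo = (mu/[D]) sum_k k(n-k)E~/(1+(n-k-1)E~)
    C(n,k) x_D^k x_A^(n-k)``; the equivalent ``f/(n x_D)`` prefactor form
    follows from ``mu/[D] = f_oligo / (n x_D)``.
    """
    if eq.oligo_fraction > 0 and pop.donor_conc == 0:
        raise UndefinedMeasurementError(
            "oligomer FRET is donor-measured: undefined for a donor-free "
            "population with a nonzero oligomeric fraction"
        )
    if pop.donor_conc == 0 or eq.oligo_fraction == 0:
        return 0.0
    s = oligomer_fret_sum(model.n, model.intrinsic_fret, pop.donor_fraction, pop.acceptor_fraction)
    return eq.oligo_fraction / (model.n * pop.donor_fraction) * s


def apparent_fret(model: OligomerModel, pop: LabeledPopulation, proximity=None) -> float:
    """Apparent (measured) FRET efficiency of a membrane region.

    Combines oligomer FRET with the density-dependent proximity-FRET
    background, weighting the latter by the non-oligomeric donor fraction:
    ``E_app = E_oligo + (1 - f_oligo) E_prox([A])``.

    Parameters
    ----------
    proximity : ProximityTable or None
        Tabulated proximity FRET vs acceptor density; ``None`` disables the
        background term.
    """
    eq = solve_monomer(pop.total_conc, model)
    e_oligo = oligomer_fret(model, pop, eq)
    if proximity is None:
        return e_oligo
    from .proximity import proximity_at

    e_prox = proximity_at(proximity, pop.acceptor_conc)
    return e_oligo + (1.0 - eq.oligo_fraction) * e_prox


def delta_g(kdiss: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Dissociation free energy ``dG = R T ln(Kdiss / Kdiss0)`` in kcal/mol.

    The standard state ``Kdiss0`` is 1 receptor per nm^2 (1e6 receptors per
    um^2); tighter-than-standard dimers have negative ``dG``.
    """
    if kdiss <= 0:
        raise ValueError(f"dissociation constant must be positive, got {kdiss!r}")
    return ctx.gas_const * ctx.temperature * np.log(kdiss / ctx.std_state_kdiss)


def assoc_const_for_fraction(n: int, total_conc: float, fraction: float) -> float:
    """Association constant putting fraction ``f`` of protomers in n-mers at ``[T]``.

    From ``f [T] = n K m^n`` with ``m = (1 - f) [T]``.  Useful for placing a
    synthetic-truth model at a prescribed point of its association curve.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if total_conc <= 0:
        raise ValueError("total concentration must be positive")
    m = (1.0 - fraction) * total_conc
    return fraction * total_conc / (n * m**n)
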