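"""Synthetic measurement generator with the structure of FSI-FRET data.

Emulates per-membrane-region triplets (donor density, acceptor density,
apparent FRET efficiency) as produced by quantitative spectral-imaging
FRET on transiently transfected cells:

* expression varies over orders of magnitude between cells (log-uniform
  per-cell mean up to a few thousand receptors/um^2) with a smaller
  log-normal spread between regions of the same cell;
* the donor/acceptor split follows the transfection ratio with per-cell
  binomial-like jitter;
* the noiseless efficiency comes from the monomer/n-mer forward model
  plus the proximity-FRET background;
* additive Gaussian noise on the efficiency (clipped to [0, 1]) and
  multiplicative log-normal noise on the recorded densities.

Defaults mirror a typical single-condition dataset: 858 regions from 286
cells pooled over 4 independent experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .equilibrium import (
    OligomerModel,
    monomer_concentration,
    _binomial_basis,
    _pair_weights,
)
from .fitting import MeasurementSet
from .proximity import ProximityTable, proximity_at

__all__ = ["GeneratorConfig", "generate", "generate_ratio_series"]


def _default_truth() -> OligomerModel:
    # dimer with E~ = 0.55 and Kdiss = 206 receptors/um^2
    return OligomerModel(n=2, intrinsic_fret=0.55, assoc_const=1.0 / 206.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Parameters
    ----------
    truth : OligomerModel
        Generating oligomer model.
    n_cells, regions_per_cell : int
        286 cells x 3 regions = 858 points by default.
    expression_range : (float, float)
        Bounds of the log-uniform per-cell mean expression, receptors/um^2.
    cell_spread : float
        Log-normal sigma of region-to-region expression within a cell.
    ratio : (float, float)
        Donor:acceptor transfection ratio, e.g. (1, 1) or (3, 1).
    label_jitter : float
        Concentration of the per-cell Beta jitter on the donor fraction
        (larger = tighter around the nominal ratio); emulates binomial
        labelling variability.
    sigma_e : float
        Additive Gaussian noise on the efficiency (absolute).
    sigma_c : float
        Log-scale sigma of the multiplicative noise on recorded densities.
    proximity : ProximityTable, optional
        Proximity-FRET background applied during generation; ``None``
        disables it.
    seed : int
        Seed of the generator stream.
    """

    truth: OligomerModel = field(default_factory=_default_truth)
    n_cells: int = 286
    regions_per_cell: int = 3
    expression_range: Tuple[float, float] = (10.0, 3000.0)
    cell_spread: float = 0.25
    ratio: Tuple[float, float] = (1.0, 1.0)
    label_jitter: float = 100.0
    sigma_e: float = 0.05
    sigma_c: float = 0.10
    proximity: Optional[ProximityTable] = None
    seed: int = 0
    condition: str = "synthetic"
    n_experiments: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.expression_range
        if not (0 < lo < hi):
            raise ValueError("expression bounds must be positive and increasing")
        if self.sigma_e < 0 or self.sigma_c < 0:
            raise ValueError("noise sigmas must be nonnegative")
        if min(self.ratio) <= 0:
            raise ValueError("ratio parts must be positive")
        if self.n_cells < 1 or self.regions_per_cell < 1:
            raise ValueError("need at least one cell and one region")


def _noiseless_efficiency(
    truth: OligomerModel,
    donor: np.ndarray,
    acceptor: np.ndarray,
    proximity: Optional[ProximityTable],
) -> np.ndarray:
    total = donor + acceptor
    x_d = donor / total
    x_a = acceptor / total
    n, k = truth.n, truth.assoc_const
    m = monomer_concentration(total, n, k)
    f = n * k * m**n / total
    s = _binomial_basis(n, x_d, x_a) @ _pair_weights(n, truth.intrinsic_fret)
    e = f / (n * x_d) * s
    if proximity is not None:
        e = e + (1.0 - f) * np.asarray(proximity_at(proximity, acceptor))
    return e


def generate(config: GeneratorConfig = GeneratorConfig()) -> MeasurementSet:
    """Generate one synthetic measurement set under the configured truth.

    Deterministic for a given configuration (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    nc, rpc = config.n_cells, config.regions_per_cell
    n_total = nc * rpc
    lo, hi = config.expression_range

    cell_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=nc))
    p_donor = config.ratio[0] / (config.ratio[0] + config.ratio[1])
    kappa = config.label_jitter
    cell_xd = rng.beta(p_donor * kappa, (1.0 - p_donor) * kappa, size=nc)

    total = np.repeat(cell_mean, rpc) * np.exp(
        rng.normal(0.0, config.cell_spread, size=n_total)
    )
    x_d = np.repeat(cell_xd, rpc)
    donor = x_d * total
    acceptor = total - donor

    e_true = _noiseless_efficiency(config.truth, donor, acceptor, config.proximity)
    e_meas = np.clip(e_true + rng.normal(0.0, config.sigma_e, size=n_total), 0.0, 1.0)
    donor_meas = donor * np.exp(rng.normal(0.0, config.sigma_c, size=n_total))
    acceptor_meas = acceptor * np.exp(rng.normal(0.0, config.sigma_c, size=n_total))

    df = pd.DataFrame(
        {
            "cell_id": np.repeat([f"c{i:04d}" for i in range(nc)], rpc),
            "region_id": np.tile(np.arange(rpc), nc),
            "donor_conc": donor_meas,
            "acceptor_conc": acceptor_meas,
            "fret_efficiency": e_meas,
            "ratio": f"{config.ratio[0]:g}:{config.ratio[1]:g}",
        }
    )
    return MeasurementSet(df, condition=config.condition, n_experiments=config.n_experiments)


def generate_ratio_series(
    config: GeneratorConfig = GeneratorConfig(),
    ratios: Sequence[Tuple[float, float]] = ((3.0, 1.0), (1.0, 1.0), (1.0, 3.0)),
) -> MeasurementSet:
    """Concatenated sets at several donor:acceptor transfection ratios.

    Each ratio reuses the base configuration with a ratio-specific derived
    seed and is tagged in the ``ratio`` column, ready for the
    FRET-vs-acceptor-fraction linearity diagnostic.
    """
    if len(ratios) < 2:
        raise ValueError("a ratio series needs at least two ratios")
    frames = []
    for i, ratio in enumerate(ratios):
        sub = replace(config, ratio=tuple(ratio), seed=config.seed + 7919 * (i + 1))
        ms = generate(sub)
        df = ms.data.copy()
        df["cell_id"] = df["cell_id"] + f"_r{i}"
        frames.append(df)
    return MeasurementSet(
        pd.concat(frames, ignore_index=True),
        condition=config.condition,
        n_experiments=config.n_experiments,
    )
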