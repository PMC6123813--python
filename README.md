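# fretolig

Quantitative FRET analysis of membrane-receptor oligomerization.

Receptor tyrosine kinases such as EphA2 associate laterally in the plasma
membrane into dimers and higher-order clusters, and the oligomeric state
controls signaling. Spectral-imaging FRET experiments measure, for each
small membrane region, a triplet: the donor-labelled receptor density, the
acceptor-labelled receptor density (both in receptors/µm²), and the
apparent FRET efficiency. `fretolig` turns collections of such triplets
into:

* the **oligomer order** *n* that best explains the data (n = 2 dimer,
  n > 2 cluster), selected by the minimum mean-squared error over
  n = 2…6;
* the **intrinsic (pairwise) FRET** Ẽ and the two-dimensional
  **dissociation constant** K
  <sub>diss</sub> = 1/K with 95% confidence intervals;
* downstream summaries: oligomeric-fraction curves, dissociation free
  energies ΔG = RT ln K<sub>diss</sub> (standard state 1 receptor/nm²),
  a FRET-vs-acceptor-fraction linearity diagnostic, and Welch/Bonferroni
  comparisons between conditions.

## Model

The apparent efficiency of a region is modelled as oligomer FRET plus a
proximity-FRET background from random (non-interacting) encounters:

```
E_app = E_oligo + (1 − f_oligo) · E_prox([A])
```

Oligomer FRET follows the kinetic theory of FRET for a binomially
labelled n-mer with a single pairwise efficiency Ẽ:

```
E_oligo = f_oligo / (n·x_D) · Σ_{k=1}^{n−1}  k(n−k)Ẽ / (1 + (n−k−1)Ẽ) · C(n,k) x_D^k x_A^{n−k}
Ẽ       = 1 / (1 + (d/R0)^6),   R0 = 54.5 Å (mTurquoise/eYFP)
```

The oligomeric fraction f_oligo comes from the mass-action
monomer ⇌ n-mer equilibrium with conservation `[T] = [m] + nK[m]^n`, so
`f_oligo = nK[m]^n/[T]`. The proximity background `E_prox(ρ)` has no
closed form for finite-size fluorophores and is tabulated by Monte Carlo:
acceptors are placed as a 2D Poisson field around a donor outside a hard
exclusion radius, and the donor quenching is `E = S/(1+S)` with
`S = Σ (R0/r_i)^6`.

Fitting proceeds exactly as the experiment demands: for each n, a grid
search over (Ẽ, K) gives the minimum MSE; the n with the lowest MSE
selects the model (a strict minimum at n = 2 identifies dimers, a minimum
at n > 2 or a flat profile identifies clusters); then nonlinear least
squares from the grid optimum refines (Ẽ, K) and yields Wald 95%
confidence intervals.

A synthetic-data module generates measurement tables with the statistical
structure of the real experiment (log-spread per-cell expression up to a
few thousand receptors/µm², donor:acceptor transfection ratios, additive
efficiency noise, multiplicative concentration noise), so the entire
pipeline is testable end to end against known ground truth.

## Worked example

Simulate a wild-type-like dimer condition (K<sub>diss</sub> = 206
receptors/µm², Ẽ = 0.55, 858 regions) and fit it:

```
fretolig proximity-table --out prox.csv --seed 0
fretolig simulate --out wt.csv --seed 1 --kdiss 206 --proximity prox.csv
fretolig fit --input wt.csv --proximity prox.csv --out wt_fit.json --mse-csv wt_mse.csv
```

The fit log reports `best n = 2 (dimer), Kdiss = 189.6`, and
`wt_fit.json` contains (abridged):

```json
{
  "mse_by_n": {"2": 0.00221, "3": 0.00240, "4": 0.00257, "5": 0.00269, "6": 0.00280},
  "best_n": 2,
  "classification": "dimer",
  "e_tilde": 0.543,  "e_tilde_ci95": [0.524, 0.562],
  "kdiss": 189.6,    "kdiss_ci95": [165.2, 222.6],
  "delta_g_kcal_mol": -5.08
}
```

Read: the MSE profile rises monotonically from n = 2, so the data are
dimer-consistent; the recovered pairwise FRET (0.543) and dissociation
constant (190 receptors/µm², CI [165, 223]) bracket the generating truth
(0.55, 206); the dimer is ~5 kcal/mol more stable than the 1-receptor/nm²
standard state. The same library calls are available in Python
(`fretolig.generate`, `fretolig.fit_oligomer_model`, …), plus
`fretolig curves` (oligomeric-fraction curve with binned data),
`fretolig linearity` (FRET vs acceptor fraction, dimer/cluster verdict)
and `fretolig compare` (Welch's t-test between two fitted
K<sub>diss</sub> with Bonferroni correction).

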