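# capbind

Quantitative analysis of mRNA-cap binding by eIF4E-family proteins:
fluorescence-titration fitting, binding thermodynamics, and
paralog-discriminating sequence analysis.

Translation initiation factor eIF4E1a and its oocyte-enriched paralog
eIF4E1b both recognize the m⁷G(5′)ppp(5′)N cap at mRNA 5′ ends, but with
different affinities and different responses to cap chemistry (N⁷
substituents, phosphate-chain length, second nucleoside, 2′-O-ribose
methylation). This package implements the full quantitative pipeline used
to characterize such differences, for biophysicists and computational
biologists working with equilibrium fluorescence titrations:

* **`binding_model`** — the single-site isotherm with ligand depletion.
  Because binding-competent protein (~0.1 μM) is comparable to ligand at
  the low end of a titration, the complex concentration is the quadratic
  root
  `[PL] = (s − √(s² − 4·[P₀ᵃᶜᵗ][L₀]))/2`, `s = [P₀ᵃᶜᵗ] + [L₀] + 1/K_as`,
  evaluated in cancellation-free form. The observable is
  `F([L₀]) = f₀ − Δf·[PL] + f_L·([L₀] − [PL])`, plus dilution and
  inner-filter corrections.
* **`titration_fit`** — bounded nonlinear least squares for
  {K_as, [P₀ᵃᶜᵗ], f₀, Δf, f_L} with analytic Jacobian, multi-start in
  K_as, curvature-based standard errors, and inverse-variance pooling of
  replicates.
* **`thermodynamics`** — ΔG° = −RT·ln K_as (1 M standard state),
  ΔΔG° transition tables with first-order error propagation, and
  eIF4E1a/eIF4E1b affinity-ratio columns; ships a measured K_as table for
  human and *Xenopus* proteins against a 13-analogue cap series.
* **`cap_ligands`** — cap-analogue name grammar (m7GTP, bn7GDP, m7GpppG,
  m7,2'OGpppG, …) and Henderson–Hasselbalch net charge vs pH from a
  configurable pK_a catalogue.
* **`sequence_features`** — columns conserved within each paralog family
  but differing between families, N-terminal charge character, and
  residue-numbering offset maps.
* **`synthetic_data`** — titration curves, replicate studies, and toy
  two-family alignments with known ground truth, so every stage runs and
  is tested without external data.

## Worked example

Fit a simulated titration and convert measured affinities into energies:

```python
from capbind import synthetic_data as sd, titration_fit as tf, thermodynamics as th

truth = sd.default_truth(kas=22.0)                    # μM⁻¹
curve = sd.simulate_titration(truth, sd.SimulationDesign(noise_sd_frac=0.01, seed=1))
fit = tf.fit_titration(curve)
print(f"K_as = {fit.kas:.1f} ± {fit.kas_se:.1f} μM⁻¹")

kas = th.read_kas_table()                             # bundled measured table
ddg = th.build_ddg_table(kas, th.read_transitions())
row = ddg.query("protein == 'heIF4E1a' and `from` == 'GTP' and to == 'm7GTP'").iloc[0]
print(f"GTP → m7GTP (heIF4E1a): ΔΔG° = {row.ddg_kcal_mol:.3f} ± {row.se:.3f} kcal/mol")
```

prints

```
K_as = 21.4 ± 2.6 μM⁻¹
GTP → m7GTP (heIF4E1a): ΔΔG° = -4.566 ± 0.048 kcal/mol
```

The fitted K_as recovers the planted 22.0 μM⁻¹ within its standard error,
and N⁷-methylation of GTP is worth about −4.6 kcal/mol of binding free
energy to human eIF4E1a — the single largest contribution of any cap
feature.

The same stages are packaged as narrative drivers:

```bash
python analysis/01_simulate_titrations.py     # synthetic replicate study + drift demo
python analysis/02_fit_affinities.py          # fit, pool, compare to ground truth
python analysis/03_thermodynamic_tables.py    # ΔΔG°/ratio/charge tables from measured K_as
python analysis/04_sequence_discrimination.py # family-discriminating residues on a toy alignment
```

writing their tables under `results/`, and as a CLI
(`capbind simulate|fit|aggregate|thermo|ratio|seqdiff|charge`).

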