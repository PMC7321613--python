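# lipotherm

Chromatographic lipophilicity, retention thermodynamics and activity
modelling for biomimetic HPLC columns.

## The problem

Reversed-phase HPLC on membrane-mimetic stationary phases — here a
glycopeptide (teicoplanin-type) phase that offers both polar and hydrophobic
interaction sites — is a fast experimental window onto how drug candidates
partition into biological interfaces. For a congeneric solute series (the
motivating application is 4-alkyl-5-aryl-1,2,4-triazole-3-thione
anticonvulsant candidates), a table of isocratic retention factors
k measured across organic-modifier fractions and column temperatures
contains, in compressed form:

* **Lipophilicity indices** from the Soczewiński–Wachtmeister model
  `log10 k = log k_w + S·φ`, where φ is the volume fraction of methanol or
  acetonitrile: the slope `S` (< 0 in RP conditions), the pure-water
  extrapolation `log k_w`, and the interpolated index `φ₀ = −log k_w / S`
  (the eluent composition at which k = 1).
* **Transfer thermodynamics** from the van't Hoff relation
  `ln k = −ΔH°/(RT) + ΔS°*/R`, giving the transfer enthalpy ΔH° and an
  entropy term ΔS°* that is biased by the unknown column phase ratio
  (R ln Φ); ΔG° = ΔH° − T·ΔS°* then carries the same constant bias and is
  comparable across solutes on one column. A linearity gate (R² > 0.9)
  flags series whose retention mechanism drifts with temperature.
* **Molecular-difference selectivity** (Chester–Coym differencing): for a
  declared pair of structural congeners, the slope of `ln α` vs `1/T`
  (α = k₂/k₁, k₂ > k₁) yields the transfer enthalpy ΔH°d of their
  molecular difference — a heteroatom swap, a methylene linker — free of
  the phase-ratio bias, gated at R² > 0.97.
* **Structure–retention–activity links**: cross-correlation (R²) of the
  derived parameters with molecular descriptors (polarizability,
  calculated log P, BBB scores, docking/DFT binding energies), and
  cross-validated classification/regression of anticonvulsant activity
  (ED50 in the maximal-electroshock assay, mg/kg; bimodal, split at
  ~350 mg/kg) from the chromatographic features.

`lipotherm` implements this chain as statsmodels-style model/results
objects, plus a synthetic-cohort generator with exported ground truth so
every stage is testable against known parameters.

## Worked example

```python
import lipotherm as lt

measurements, truth = lt.generate_cohort(seed=1)   # 14 compounds, MeOH + ACN
iso = measurements[measurements.temperature == truth.t_ref]

lipo = lt.SoczewinskiModel(iso).fit()
print(lipo.to_frame()[["compound_id", "modifier", "S", "log_kw", "phi0", "fit_r2"]].head(4))
print(lipo.similarity_regression("MeOH").summary())
```

```
compound_id modifier         S   log_kw     phi0   fit_r2
        C01      ACN -3.539128 1.503989 0.424960 0.999439
        C01     MeOH -2.735006 1.667672 0.609751 0.998381
        C02      ACN -4.642613 1.876898 0.404276 0.999637
        C02     MeOH -3.588603 2.027047 0.564857 0.999084
y = -0.400992(±0.08027) x + 0.49742(±0.2579)
n = 14, R^2 = 0.9080, F = 118.4795, s_e = 0.0793604
```

Each compound/modifier series gives its solvent-strength slope `S`, the
water-extrapolated `log k_w` and the interpolated `phi0`; the similarity
regression of `log k_w` on `S` (R² ≈ 0.91 for the methanol system here) is
the standard check that one retention mechanism governs the whole series.
The ± terms are 95% confidence half-widths.

Continuing with the temperature series:

```python
thermo = lt.VantHoffModel(measurements[measurements.phi == truth.phi_ref]).fit()
print(thermo.to_frame().head(2))
sel = lt.SelectivityModel(measurements[measurements.phi == truth.phi_ref], truth.pairs).fit()
print(sel.to_frame().head(2))
```

```
compound_id modifier  phi  dH_kJ_mol  dS_star_J_mol_K  dG_kJ_mol       r2  linear_ok
        C01      ACN 0.15  -7.852911        -8.092849  -5.480492 0.987849       True
        C01     MeOH 0.15 -15.457079       -28.599565  -7.073117 0.998285       True
id_low id_high modifier  dHd_kJ_mol       r2  linear_ok
   C01     C02      ACN   -2.787052 0.995874       True
   C01     C02     MeOH   -3.765366 0.998012       True
```

Transfer into the stationary phase is exothermic (ΔH° ≈ −15 kJ/mol in
methanol) and enthalpy-driven (ΔG° ≈ −7 kJ/mol at 293.15 K); the C01/C02
heteroatom pair's molecular difference contributes ≈ −3.8 kJ/mol of
transfer enthalpy in the methanol system, less in acetonitrile.

The same objects feed descriptor correlation and activity models; the
one-shot pipeline is

```bash
lipotherm run-all --out bundle --seed 1          # or: lipotherm simulate / fit-lipo / ...
```

which writes Table-shaped CSVs (lipophilicity, thermodynamics, selectivity,
ΔΔG°, correlation), JSON model reports, and provenance (config hash, seed,
version).

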