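# cdftprof

Conceptual-DFT reactivity profiling and pharmacokinetics rule interpretation
for small-molecule screening campaigns.

The package targets the common *in silico* workflow around natural-product
leads — here, five phytoligands from *Acorus calamus* rhizome extract
(S-adenosylhomocysteine, carbenicillin, apiin, rutin ("Rutine"), and
chloramphenicol monoglucuronide) screened against Alzheimer's-disease
protein targets. It covers every desk-side stage of that workflow:

* **Global reactivity descriptors** from vertical ionization energy *I* and
  electron affinity *A* (Koopmans-type, *I* = −ε<sub>HOMO</sub>,
  *A* = −ε<sub>LUMO</sub>, or ΔSCF from total energies):

  χ = (I+A)/2, η = I−A, ω = χ²/2η, S = 1/η,
  N = ε<sub>HOMO</sub> − ε<sub>HOMO</sub>(TCE),
  ω⁻ = (3I+A)²/16η, ω⁺ = (I+3A)²/16η, Δω± = ω⁻+ω⁺,

  plus the Domingo strong/moderate/marginal electrophilicity scale and
  "Koopmans in DFT" (KID) consistency diagnostics
  J<sub>I</sub>, J<sub>A</sub>, J<sub>HL</sub>.
* **Local descriptors** on cube-format electron densities: finite-difference
  Fukui functions f⁺ = ρ<sub>N+1</sub>−ρ<sub>N</sub>,
  f⁻ = ρ<sub>N</sub>−ρ<sub>N−1</sub>, the dual descriptor Δf = f⁺−f⁻,
  condensed-to-atom indices from population charges, and sign-region
  summaries.
* **Pharmacokinetics rules**: Molinspiration-style bioactivity-score
  classification and a data-driven ADMET rulebook (Caco-2, intestinal
  absorption, skin log Kp, BBB log BB, *T. pyriformis* toxicity, plus
  pass-through boolean panels).
* **Docking analytics** over binding-affinity tables (kcal/mol): global
  extremes, best ligand per protein target, per-ligand means.
* **Assay math**: Ellman percent inhibition, four-parameter-logistic IC50
  fitting, and the Scherrer crystallite-size formula.
* **Synthetic generators** for every input (KID-consistent species tables,
  Gaussian-blob density triplets with exact electron counts, ADMET tables,
  noisy dose-response curves), so the whole pipeline is testable offline.

## Worked example

```python
from cdftprof import IonizationData, global_descriptors, electrophilicity_class

# Rutin: I and A recovered from its published chi = 4.1346 eV, eta = 4.1184 eV
ia = global_descriptors(IonizationData(I=6.1938, A=2.0754, method="koopmans"))
print(f"omega = {ia.omega:.4f} eV  ({electrophilicity_class(ia.omega)})")
print(f"omega- = {ia.omega_minus:.4f}  omega+ = {ia.omega_plus:.4f}  "
      f"net = {ia.net_electrophilicity:.4f}")
```

prints

```
omega = 2.0754 eV  (strong)
omega- = 6.4756  omega+ = 2.3410  net = 8.8165
```

— rutin is a strong electrophile (ω > 1.5 eV) whose electrodonating power
dominates its electroaccepting power, as expected for a polyphenol glycoside.

The same panel is available from the shell:

```bash
cdftprof synth species --seed 0 --out-dir fixtures/
cdftprof global --species fixtures/species.csv --out descriptors.csv
cdftprof pharma --docking src/cdftprof/data/table1_docking.csv
cdftprof scherrer --fwhm-deg 0.23 --two-theta-deg 30.1
```

The `profile` subcommand chains every stage from a JSON config and renders a
combined JSON or markdown report.

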