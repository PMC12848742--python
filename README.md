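# ptpkit

Analysis toolkit for engineered archaeal **protein tyrosine phosphatases
(PTPs)** — small cysteine-nucleophile enzymes whose phosphate-binding
P-loop, unusually mobile in hyperthermophilic archaea, couples loop
conformation to catalysis, active-site hydration and oxidative
vulnerability. The package is written for structural bioinformaticians
and enzymologists who want a tested, scriptable version of the bespoke
computational layer used in such studies:

* **Chimeric sequence shuffling** — design a chimera from an aligned set of
  progenitor sequences: at a conserved alignment column the single residue
  is kept; at a variable column one residue is drawn uniformly over the
  *distinct* states (unweighted by occurrence), with substitution and
  percent-identity accounting against each progenitor.
* **Dihedral-space loop analysis** — the angleRMSD similarity between a
  trajectory frame and a reference loop conformation,

  $$\mathrm{angleRMSD} = \frac{1}{N}\sum_{i}^{\text{loop}}
  \sqrt{(\Phi_i-\phi_i)^2 + (\Psi_i-\psi_i)^2},$$

  with all angle differences wrapped into (−180°, 180°]; nearest-reference
  state classification (active/low, intermediate, inactive/high), 2-D
  conformational histograms, RMSF, Kabsch-superposed backbone RMSD.
* **Active-site hydration** — water counts in a probe sphere (default 5 Å)
  around the nucleophilic cysteine sulfur, occupancy histograms and tail
  probabilities P(≥ k waters); integration of externally produced
  solvation free-energy voxel grids inside the analysis sphere; a
  bridging-water criterion (≤ 3.5 Å to both a carboxylate oxygen and the
  phosphoenzyme phosphorus) for catalytic-backup candidates.
* **Noncovalent-interaction census** — per-frame % residues engaged in
  hydrophobic contacts, salt bridges, side-chain hydrogen bonds and
  cation-π pairs, plus α-helix content from a φ/ψ window with a
  4-residue run rule.
* **Sequence thermostability descriptors** — composition, Kyte–Doolittle
  hydrophobic fraction, GRAVY, Ikai aliphatic index, Guruprasad
  instability index.
* **Kinetics and thermodynamics** — Michaelis–Menten fits; the bell
  pH-rate profile
  $k_\mathrm{cat} = k_\mathrm{cat}^\mathrm{lim} / (1 + [\mathrm{H^+}]/K_{E1} + K_{E2}/[\mathrm{H^+}])$;
  Arrhenius fits; pseudo-first-order peroxide-inactivation fits
  (k_obs → k_inact); transition-state-theory barriers
  $\Delta G^\ddagger = RT\,\ln(k_B T / h k)$; denaturation-enthalpy
  scaling with molecular mass.

A first-class **synthetic-data generator** (`ptpkit.synth`) produces
alignments with controlled conservation, two-state Markov loop
trajectories realised as 3-D backbones, Poisson-hydration frames,
kinetic datasets with known truth and exact-geometry toy active sites,
so every analysis stage is testable without downloads or MD engines.

## Worked example

Fit a simulated bell-shaped pH-rate profile (13 points, pH 3.5–6.5, 1 %
multiplicative noise, true pK values 4.2 / 5.4) and convert a turnover
number to an activation free energy:

```python
import numpy as np
from ptpkit import synth, kinetics

spec = synth.KineticSimSpec(
    "bell_ph", {"kcat_lim": 10.0, "pk_e1": 4.2, "pk_e2": 5.4},
    design_points=np.linspace(3.5, 6.5, 13), noise_cv=0.01, seed=1,
)
ds = synth.make_kinetics_dataset(spec)
fit = kinetics.bell_fit(ds.data["pH"], ds.data["kcat"])
print(f"pK_E1 = {fit.params.pk_e1:.2f}, pK_E2 = {fit.params.pk_e2:.2f}, "
      f"kcat_lim = {fit.params.kcat_lim:.2f} /s, pH optimum = {fit.params.ph_optimum:.2f}")
dg = kinetics.tst_activation_free_energy(8.6, 298.15)
print(f"TST barrier for kcat = 8.6 /s at 298.15 K: {dg:.2f} kcal/mol")
```

prints

```
pK_E1 = 4.21, pK_E2 = 5.39, kcat_lim = 10.16 /s, pH optimum = 4.80
TST barrier for kcat = 8.6 /s at 298.15 K: 16.18 kcal/mol
```

The recovered pK values sit within 0.01–0.02 units of the generating
truth; the pH optimum is the mean of the two pK values; the barrier is
what transition-state theory assigns to a 8.6 s⁻¹ turnover at 25 °C.

The same analyses are available from the shell via the `ptpkit` console
script (`simulate`, `shuffle`, `seqfeat`, `loops`, `solvation`,
`contacts`, `kinetics` subcommands, each writing CSV/FASTA/PDB outputs
plus a provenance record).

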