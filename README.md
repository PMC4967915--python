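# calyxsim

Desk-scale analytics for ligand unbinding from calyx (lipocalin-type)
proteins, built around the apolipoprotein M / sphingosine-1-phosphate
(apoM–S1P) system: apoM's eight-stranded β-barrel encloses a cup-shaped
binding pocket (the calyx) from which the signalling lipid S1P must be
extracted before it can activate its receptor.

The package couples a fully synthetic data layer with the analysis
machinery used to characterise such unbinding studies, so every method can
be exercised and validated against known ground truth on a laptop:

- **`landscape_sim`** — model 1-D unbinding free-energy profiles U(ξ) along
  the ligand–protein separation ξ (bound ≈ 1 nm, free plateau at 3.3 nm),
  overdamped Langevin sampling (unbiased, harmonic umbrella at
  k = 1000 kJ/mol/nm², or constant-velocity moving spring at v = 0.01 nm/ns,
  k = 100 kJ/mol/nm²), toy calyx structures with analytically known cavity
  volumes, and atom-pairwise force records with designed residue means.
- **`wham_pmf`** — weighted histogram analysis method (WHAM): the
  self-consistent estimator combining the biased window histograms into the
  unbiased potential of mean force (PMF), with window-level bootstrap
  errors (200 replicates) and ΔG/barrier summaries.
- **`fda_forces`** — force-distribution analysis: residue-wise
  time-averaged ligand–protein force profiles from atom-pair force tables,
  key-residue thresholds (>70 pN equilibrium, >40 pN pulling) and
  equilibrium-vs-pulling contrasts.
- **`protonation`** — titratable-group bookkeeping: effective pKa from
  environmental perturbation terms, Henderson–Hasselbalch protonated
  fractions, net proton exchange upon unbinding, isoelectric points, and
  their time series.
- **`pocket_geometry`** — structure analytics: Cα opening distances, Kabsch
  RMSD and windowed RMSF, the Tyr102/Tyr147 gate separating the hydrophilic
  upper and hydrophobic lower sub-pockets, hydrogen-bond occupancy, and
  grid/probe/flood-fill cavity volumes partitioned by the gate plane.
- **`cli`** — a `calyxsim` command orchestrating the whole synthetic study
  from a YAML config.

## The statistics at the core

Umbrella window *i* restrains ξ with bias w_i(ξ) = k/2 (ξ − c_i)².  WHAM
iterates

    P(ξ_b) = Σ_i h_i(b) / Σ_i N_i exp[(f_i − w_i(ξ_b)) / k_BT]
    f_i    = −k_BT ln Σ_b P(ξ_b) exp[−w_i(ξ_b) / k_BT]

to self-consistency and reports W(ξ) = −k_BT ln P(ξ), gauged to zero at its
minimum.  Errors come from resampling complete windows with replacement and
re-solving per replicate.  The net proton exchange of a ligand with
titratable groups g upon unbinding is

    n = Σ_g [θ(pKa_free,g, pH) − θ(pKa_bound,g, pH)],  θ = 1/(1+10^(pH−pKa)).

## Worked example

```python
import calyxsim as cs

land = cs.make_unbinding_landscape(barrier=64.0)          # kJ/mol
params = cs.LangevinParams(n_steps=1_111_120, seed=1)
windows = cs.generate_umbrella_dataset(
    land, cs.default_umbrella_centers(), params)          # 47 windows
cfg = cs.WHAMConfig()
profile = cs.solve_wham(cs.build_histograms(windows, cfg), cfg)
print(cs.pmf_summary(profile))

bound, free = cs.s1p_reference_sets()
print(cs.net_proton_exchange(bound, free, pH=7.0))
```

prints (seed 1)

```
{'delta_g_unbind': 63.966928109020834, 'barrier': 64.90679309341756,
 'xi_min': 1.005, 'xi_plateau': 2.275, 'plateau_found': True}
0.17972028981917
```

i.e. the reconstructed PMF recovers the 64 kJ/mol input barrier to well
within statistical error (the unbinding free energy is the mean PMF over
the detected free-state plateau), and with the reference pKa values
(phosphate oxygens ≈4 carrier-bound vs ≈6 free; amine 14 vs 11) the ligand
exchanges |n| ≈ 0.18 protons at pH 7 — protonation is essentially unchanged
by unbinding, consistent with a constant net ligand charge of −1 e.

The same study runs end to end from the shell:

```
calyxsim run-all --seed 1 --outdir out/
```

writing per-stage TSV/JSON artifacts plus `out/report.json` with the
headline numbers (ΔG, barrier, rupture force, key residues, |n|, pI,
gate distance, cavity volumes).

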