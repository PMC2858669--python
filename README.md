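# npcharge

Charge and hydrophobicity profiling of nuclear transport, and a
screened-Coulomb model of the electrostatic energetics of translocation
through the nuclear pore complex (NPC).

## The problem

NPCs are selective filters: transport receptors (importins/exportins) and
their cargo complexes cross in milliseconds, while most soluble proteins
above ~30–40 kDa are excluded. Receptor surfaces are unusually hydrophobic
— and, as sequence profiling shows, unusually *negatively* charged, while
the FG-nucleoporin domains that form the permeability barrier are net
positive (their lysine-rich spacers separate the hydrophobic FG-repeats).
`npcharge` provides the full analysis chain behind this picture, for
computational biologists who want to place their own proteins in the same
coordinate system:

1. **Sequence profiling** — net charge at fixed pH from the
   Henderson–Hasselbalch sum over every ionizable group
   (`Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`, in
   elementary charges, EMBOSS-style pKas), isoelectric point by bisection,
   and length-normalized means over a bundled registry of 27 published
   hydrophobicity scales plus Grantham polarity.
2. **Aggregate hydrophobicity axis** — PCA of the z-scored scale panel;
   PC1 (which captures ~75–80 % of the variance) is the single
   hydrophobicity coordinate, sign-anchored to Kyte–Doolittle.
3. **Regime classification** — quadrants of the (net charge, aggregate
   hydrophobicity) plane: negative + hydrophobic = translocation
   competent; positive + hydrophilic = cargo-like (or barrier-like for
   nucleoporins). Large proteins in the competent quadrant are flagged as
   predicted self-translocators (the beta-catenin case).
4. **Electrostatic energetics** — Debye–Hückel screened Coulomb
   interaction between a particle of charge `Q_NTR` and the local
   nucleoporin charge `Q_NPC` within one screening length (λ ≈ 1 nm):
   `ΔH = Q_NTR·Q_NPC·e²/(4πε₀ελ)` in units of k_BT, with
   `ΔG = ΔH − TΔS` for a user-supplied entropic confinement cost. With
   the default yeast pore (19 × 37 nm cylinder, 13 FG-nucleoporin species
   × 8 copies) this linearizes to ΔH ≈ 0.05·Q_NTR k_BT.
5. **Synthetic cohorts** — a seeded generator for receptor-like,
   cargo-like, FG-domain-like (explicit FxFG/GLFG repeats with
   lysine-rich spacers) and proteome-background sequence classes, so the
   entire pipeline is testable without any downloads.

## Worked example

```python
from npcharge import GeneratorConfig, NPCModel, PropertySpace, generate_cohort

records = generate_cohort(GeneratorConfig(seed=1))   # 313 labeled proteins
results = PropertySpace(records).fit()
print(results.summary())
```

```
Property-space model of charge and hydrophobicity
==========================================================
subjects               : 313 (313 proteins, 0 complexes)
properties             : 30 (27 hydrophobicity scales)
pH for net charge      : 7.2
PC1 variance fraction  : 0.816
PC2 variance fraction  : 0.099
charge threshold       : +0.0 e
hydrophobicity thresh. : +0.392 (background median)

per-class means (net charge e | aggregate hydrophobicity):
  background         n=200      -3.80 |  +0.333
  cargo_like         n=50      +29.34 |  -4.680
  fg_nup_like        n=13      +56.39 | -10.631
  receptor_like      n=50      -62.06 |  +6.110

regime counts:
  translocation_competent  114
  other                    100
  cargo_like               86
  fg_barrier_like          13
```

The aggregate axis alone carries 82 % of the hydrophobicity variance;
receptor-like proteins are strongly acidic and hydrophobic, cargo-like
proteins basic and hydrophilic, and all 13 synthetic FG-domains land in
the barrier-like quadrant. The electrostatic model then prices each
particle's pore entry:

```python
print(NPCModel().summary())
```

```
NPC electrostatic model
-----------------------------------------------
pore cylinder          : r = 19.0 nm, h = 37.0 nm
pore volume            : 41962.3 nm^3
FG-nucleoporin census  : 13 species x 8 copies
screening length       : 1.0 nm
dielectric constant    : 80.0
temperature            : 298.15 K
local charge Q_NPC     : 0.0727 e
coupling dH/dQ_NTR     : +0.0509 k_B T / e
```

So a particle carrying −50 e (a typical transport receptor) gains
~2.5 k_BT of electrostatic enthalpy on entering the pore, a +52 e
particle (a linker histone alone) faces a ~+2.6 k_BT barrier, and each
phosphorylation site shifts the barrier by ~0.05 k_BT.

A command-line interface mirrors the library:
`npcharge simulate | profile | pca | space | heatmap | classify | energy`
(see `npcharge --help`).

## Layout

- `src/npcharge/io.py`, `scales.py` — FASTA/manifest I/O, residue-scale registry
- `src/npcharge/ionization.py`, `profiler.py` — charge, pI, property matrices
- `src/npcharge/axes.py` — PCA, correlation, clustering, heat maps
- `src/npcharge/electrostatics.py` — the screened-Coulomb NPC model
- `src/npcharge/regimes.py` — quadrant classification, self-translocators
- `src/npcharge/synthetic.py` — seeded cohort generator
- `src/npcharge/model.py` — `PropertySpace` / `PropertySpaceResults` front end
- `docs/methods.md` — model assumptions, parameter choices, limitations
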