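# Methods

## Net charge and isoelectric point

The net charge of a chain at pH is the sum over every ionizable
side-chain occurrence (C, D, E, H, K, R, Y) plus one amino- and one
carboxyl-terminus of the Henderson–Hasselbalch fractional charge,

    Q(pH) = Σ_basic 1/(1 + 10^(pH − pKa)) − Σ_acidic 1/(1 + 10^(pKa − pH)),

in elementary charges. The default pKa set follows the EMBOSS `iep`
convention (N-terminus 8.6, C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1) so that charges are reproducible across
installations; every value is overridable from a YAML config. Histidine
is treated as a basic group and therefore contributes fractionally
(~0.16 e) at the working pH of 7.2 (intracellular). Q is strictly
decreasing in pH, so the isoelectric point is found by bisection on
[0, 14] (default tolerance 10⁻⁶ e, 200-iteration cap); no derivative
code is needed and convergence is guaranteed.

Two numerical caveats are intentional. First, `Q(pH)` is exact at the
ends of the pH scale only in the limit: arginine (pKa 12.5) still holds
~0.09 e at pH 13.5, so "fully deprotonated" checks are meaningful only
for short, R-free sequences. Second, complexes are treated as
non-covalent assemblies: every member chain keeps both termini, and the
complex charge is the copy-weighted sum of member charges (the complex
pI is the root of that summed curve).

## Property profiles and normalization

Each per-residue property of a protein is the mean of a residue scale
over its sequence — a pure composition statistic, invariant under
reordering, with no solvent-accessibility weighting (structures are not
assumed). A complex's per-residue properties are the copy-and-length
weighted means of its members, identical to profiling the concatenated
sequence. The property matrix (subjects × properties) supports three
states: `raw`, `centered` (column means removed), and `zscored`
(additionally divided by the population standard deviation). The heat
map and the PCA both operate on the z-scored state; the display clips
the color scale at ±3 SD (bright red/green). Zero-variance columns are
a hard error naming the column, as is normalizing fewer than two
subjects.

## The residue-scale registry

The bundled registry (`data/residue_scales.tsv`) compiles 27 widely
published per-residue hydrophobicity scales — Kyte–Doolittle,
Hopp–Woods, the Eisenberg consensus, Fauchère–Pliska, Janin,
Engelman GES, the two Wimley–White transfer scales, Rose buried
fraction, Chothia, Bull–Breese, Guy, Miyazawa–Jernigan, Roseman,
Wolfenden hydration, Black–Mould, Abraham–Leo, Cowan–Whittaker,
Manavalan–Ponnuswamy, Sweet–Eisenberg OMH, Nozaki–Tanford, Aboderin,
Zimmerman, Meek, Rao–Argos, Parker, Levitt — plus the Grantham polarity
scale. It is a curated compilation transcribed from the standard
compendia; individual entries may differ at the margins from the
original papers, and the TSV file is the single source of truth (any
registry with ≥1 hydrophobicity scale and the same file format can be
substituted). Scales keep their published orientation; because the PCA
operates on the correlation structure of z-scored columns, a
hydrophilicity-oriented scale only flips the sign of its loading and
leaves every variance fraction unchanged.

## Aggregate hydrophobicity

PCA is computed on the z-scored hydrophobicity columns (full SVD, all
components kept, so variance fractions sum to 1 and loadings are
orthonormal). PC1 is the aggregate hydrophobicity axis; its sign is
fixed by requiring a positive loading on a reference scale
(Kyte–Doolittle by default), so hydrophobic = high. By default the axis
is fitted on the assembled subject set itself; a pre-fitted axis can be
supplied to project new subjects using the stored training column
means/SDs. On proteome-background cohorts the first component carries
~78–82 % of the panel variance, and Grantham polarity anticorrelates
with it strongly (signed r² ≈ −0.92 to −0.94), which is why the pair
(net charge, aggregate hydrophobicity) suffices as a 2D summary.

Row clustering for the heat map is agglomerative with Euclidean
distance; the linkage method defaults to `average` (the common choice
for profile heat maps) and is configurable
(single/complete/average/ward). Ties are broken deterministically by
input row order.

## Regime classification

The plane is cut into quadrants at charge 0 e (the physically natural
boundary) and at the median aggregate hydrophobicity of a designated
background cohort (defining "high" hydrophobicity without inventing a
constant). Negative + hydrophobic ⇒ `translocation_competent`;
positive + hydrophilic ⇒ `cargo_like`, or `fg_barrier_like` when the
subject carries a nucleoporin/FG label; everything else, including
points exactly on a boundary, ⇒ `other`. Subjects classified
translocation-competent are reported as predicted self-translocators,
with molecular weight (average residue masses via Biopython) compared
against a 40 kDa passive-diffusion limit — large flagged proteins are
the interesting predictions.

## The electrostatic model

The pore is a cylinder (radius 19 nm, height 37 nm ⇒ volume
4.20 × 10⁴ nm³) containing 13 FG-nucleoporin species at the
conservative copy number of 8. The local charge a particle surface sees
is a uniform-density expectation: the 104 nucleoporins contribute the
fraction of their median charge that falls inside a hemisphere of one
screening length,

    Q_NPC = (13 × 8) × q_median × ((2/3)πλ³ / πr²h),

with λ = 1 nm. The default median FG-nucleoporin net charge is +14 e,
representative of lysine-rich FG-domains at pH 7.2; it yields
Q_NPC = 0.073 e and a per-unit-charge coupling of 0.051 k_BT/e. An
explicit charge list (its median is used) or a direct `q_npc_e` value
may be supplied instead — the latter is useful for imposing an exact
coupling. The pair energy is the screened Coulomb expression
`Q₁Q₂e²/(4πε₀ελ)` converted to k_BT (CODATA constants via
`scipy.constants`); at unit charges, λ = 1 nm, ε = 80 and T = 298.15 K
(room temperature — the default, since the physiological value changes
the coupling by <2 %) it evaluates to 0.7006 k_BT, the Bjerrum-length
check. The enthalpy is linear in the particle charge, so one added
negative charge (one phosphorylation site, −1 e by convention rather
than a physiological −1.5 e) shifts ΔH by ~0.05 k_BT, and a −50 e
receptor-scale particle gains ~2.5 k_BT.

The model is deliberately order-of-magnitude: Debye–Hückel screening
(no nonlinear Poisson–Boltzmann corrections), no structural charge
distribution, and no computation of the entropic confinement cost TΔS,
which enters only as a user-supplied number in ΔG = ΔH − TΔS. No
kinetic quantities are predicted.

## Synthetic cohorts

The generator emulates four composition classes on top of
proteome-average residue frequencies (bundled,
`data/background_frequencies.tsv`):

- `receptor_like`: D, E, L, I, F, V boosted ×1.6 and renormalized;
  lengths log-normal with median 1000 residues (shape 0.25), the
  importin-β size range. Mean net charge ≈ −62 e at pH 7.2.
- `cargo_like`: K, R boosted ×1.6; lengths log-normal median 450
  (shape 0.45). Mean net charge ≈ +29 e.
- `fg_nup_like`: built structurally, not i.i.d. — exactly n FxFG or
  GLFG motifs (n log-normal, median 28) alternating with spacers drawn
  from a hydrophilic profile (no F/W/Y/C; L/I/V/M at ×0.25; D/E at
  ×0.5; K ×2.0; S/N/T/Q/G ×1.5; spacer lengths log-normal median 12).
  Confining phenylalanine to the motifs makes repeat counts exact by
  construction, and the lysine-rich spacers make the domains net
  positive and hydrophilic, as real FG-domains are.
- `background`: plain proteome-average sampling, median length 450.

Default cohort sizes are 50/50/13/200 (13 mirroring the FG-nucleoporin
census); all lengths are clamped at ≥20 residues, and everything is
reproducible byte-for-byte from the config and a single integer seed.
These cohorts reproduce the qualitative structure of the real data —
class separation in the 2D space (≥90 % quadrant recovery), PC1
dominance, the polarity anticorrelation — but they are i.i.d.
composition models: they contain no domain architecture, no homology
structure, no real receptor/cargo pairs, and their charge separation is
built in by the boost factors. Passing tests therefore validate the
pipeline's mechanics and the model arithmetic, not the biological
claim; reproducing the original protein-set numbers requires fetching
the named sequences (helper: build FASTA + label tables and feed them
to `PropertySpace.from_fasta`).

## Problem sizes

The test suite and the acceptance script run on the default cohorts
(313 subjects) and a 500-protein background cohort; both complete in
seconds on one core. Larger cohorts scale linearly in subjects ×
scales.
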