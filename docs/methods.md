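# Methods

## Model

Each descriptor is modelled as an additive function of atom-centered group
counts and whole-molecule special-group counts,

Y = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ + C,

evaluated at 298.15 K / 100 kPa. The model is purely topological: group
assignment uses connectivity, bond orders, formal charges and ring
membership, never 3D coordinates. Inputs are assumed to be curated to the
reference temperature; no temperature adjustment is performed.

## Group centers and the descriptor grammar

An atom is a group center when it carries at least two substituents (heavy
neighbours plus hydrogens). Hydrogens, halogens and atoms attached through
a lone multiple bond (carbonyl/nitro/N-oxide oxygens, thiono sulfur,
nitrile and terminal azide nitrogens) are terminal: they appear inside
their neighbour's descriptor only. This mirrors the packaged vocabulary,
which contains no halogen or terminal-atom center rows, and it means the
partition property "every center typed exactly once" deliberately excludes
terminal atoms.

Atom types encode element, hybridization and center charge: `C sp3/sp2/sp/
aromatic`, likewise for N with a `N(+)` prefix when positively charged,
divalent `O`, divalent `S2` vs hypervalent `S4` (any double bond or more
than two substituents), trivalent `P3` vs `P4`, and plain `B`, `Si`.
Hybridization is derived from Kekulé bond orders alone (a triple bond or
two cumulated doubles → sp; one double → sp2; otherwise sp3), so e.g. amide
nitrogens are sp3 centers with a π annotation, which is how the vocabulary
spells them.

Neighbour descriptors list implicit hydrogens first, then one token per
heavy neighbour: `[marker][element][charge]` with markers `''/=/#/:` for
single/double/triple/aromatic bonds and iodine written `J`. Tokens sort by
element priority B < C < N < O < S < P < Si < F < Cl < Br < J, then marker
priority, and aggregate (`:C2`, `H3C`). Neighbour charges are normalized to
one net charge per element, rendered after that element's last token
(`CO=O(-)`). This makes matching independent of where a printed spelling
hangs the charge -- relevant for a handful of table rows (e.g. `CN2F(+)`)
where the charge floats to the end of the spelling; the parser re-attaches
such floating charges to the last chargeable (non-halogen) element. The
canonicalisation is verified to be collision-free over all 1074 printed
group rows.

### Aromaticity

Typing aromaticity covers six-membered aromatic rings only. Five-membered
heteroaromatics are typed from their Kekulé structure: thiophene sulfur is
`S2|C2(2pi)`, furan oxygen `O|C2(2pi)`, pyrrole NH `N sp3|HC2(2pi)`, and
their ring carbons are sp2 (`H=CS`, `H=CO`, `H=CN`, `HC=C`). This is the
convention the packaged vocabulary uses -- it contains these Kekulé
spellings with large occurrence counts and no aromatic-marker spellings
involving O or S. Toolkit (RDKit) aromaticity, which does include
five-membered rings, is retained separately on bonds and used where ring
*rigidity* matters: delocalized ring bonds are excluded from the endocyclic
single-bond count and their atoms from the angle-strain counts.

### π annotation

For neutral `N sp3`, `O` and `S2` centers, a trailing `(kpi)` counts
neighbours engaged in a π system (aromatic, or carrying any double/triple
bond). Phenol oxygen is `O|HC(pi)`, an ester ether-oxygen `O|C2(pi)`,
diphenyl ether `O|C2(2pi)`. Other center types carry no annotation, again
following the vocabulary.

### Special groups

- **H/H Acceptor** -- intramolecular hydrogen-bond correction. Chosen motif
  (the source procedure names the group but not its detection rule): a
  donor heteroatom (N/O/S with ≥1 H) and an acceptor (N/O, uncharged or
  negative, not valence-saturated) separated by exactly 3 or 4 bonds,
  closing a 5- or 6-membered H-bonded ring; each unordered donor-acceptor
  pair counts once. Counting pairs (not donor hydrogens) makes ethylene
  glycol count 1, matching the worked fixtures.
- **Alkane / Unsaturated HC, No. of C atoms** -- for molecules containing
  only C and H: one count per carbon, "Alkane" when fully saturated,
  "Unsaturated HC" when any multiple bond or aromatic ring is present.
- **Endocyclic bonds** -- single-order ring bonds; aromatic/delocalized
  bonds never count (higher-order and delocalized bonds are already
  rotationally restricted).
- **Angle60 / Angle90 / Angle102** -- per-atom strain counts for atoms whose
  smallest non-aromatic ring has size 3 / 4 / 5. The per-atom unit and the
  aromatic-ring exclusion are this package's reading: the source leaves the
  unit undefined, and the liquid-crystal table's Angle102 support (138
  molecules) is far below its thiophene-containing population (314
  molecules), ruling out counting delocalized five-rings.

### Charge conventions

Nitro, azide and amine-oxide groups are normalized to charge-separated
form before typing (the vocabulary spells these only as `N(+)...O(-)`).
Sulfoxides, sulfones and phosphine oxides are deliberately left in their
double-bonded form (`S4|C2=O`, `P4|C3=O`), so the toolkit's default
normalizer -- which would charge-separate them -- is replaced by a minimal
three-rule set.

## Prediction gating

A group is valid when its contribution cell is non-blank and its molecule
support is ≥ `min_support` (default 3). A molecule containing any invalid
or unknown atom group, or an invalid special group, is unpredictable; the
refusal names the groups. Special groups entirely absent from a
descriptor's table (e.g. the hydrocarbon corrections for the entropy
models) are not terms of that descriptor's model and are ignored. Elements
outside {H, B, C, N, O, P, S, Si, halogens} give a distinct
"out of element scope" status. Contributions are summed in sorted-key
order so predictions are bit-for-bit reproducible and exactly match any
oracle summing in the same canonical order.

The fusion enthalpy is ΔH°sub − ΔH°vap with uncertainty
√(σ_sub² + σ_vap²) = √(11.39² + 4.56²) = 12.27 kJ/mol from the packaged
cross-validation deviations.

## Fitting

The normal equations (XᵀX)β = Xᵀy are solved by Gauss-Seidel iteration:
zero start, sweeps in canonical column order, convergence when the largest
scaled coefficient change |Δβ|/(1+|β|) drops below 1e-10, cap 2·10⁵
sweeps. For full-rank designs the normal matrix is symmetric positive
definite, where Gauss-Seidel converges unconditionally; the test suite
anchors correctness to a direct least-squares factorization (agreement to
1e-6 relative), so the iteration scheme is an implementation detail, not a
correctness assumption. Rank deficiency is flagged (`unique=False`);
all-zero columns raise with the column named.

Gating before fitting drops groups below the support threshold *and* the
molecules containing them, iterated to a fixed point (removing molecules
can push further groups below threshold; the fixed point is the only
self-consistent reading of the gate). The outlier loop removes records
whose full-fit residual exceeds k times the cross-validated standard
deviation (k = 4 for the vaporization/sublimation enthalpies, 3 for the
entropy models; none for solvation) and refits, at most 5 rounds.

## Cross-validation and statistics

10-fold cross-validation with uniform random fold assignment by record
(no stratification), seeded and reproducible. Each fold refits with the
support gate re-applied inside the fold; held-out records whose groups are
not usable in that fold are excluded from the statistics and counted --
this is why the cross-validated N is below the training N. Definitions:
training R² is the squared Pearson correlation; Q² = 1 − PRESS/SS_tot with
the full-data mean; "Deviation Standard" is √(Σr²/N) without
degrees-of-freedom correction; "Deviation Average" is mean |r|; the
reported regression line is calculated-on-experimental. Outlier removal
happens on the full fit before the final cross-validation.

## Synthetic data

The generator realises the additivity model directly: integer group counts
(0-4 per key), known coefficients, Gaussian noise, seeded. The default
spec uses 20 common vaporization contributions as ground truth and a noise
standard deviation of 4.5 kJ/mol -- the order of that model's
cross-validated deviation -- with n = 500 records, the size at which the
package's recovery checks run (coefficient RMSE ≈ 0.14, held-out sigma
within a few percent of the generating noise over 20 seeds). Synthetic
records are abstract count vectors: they exercise the solver, gating and
cross-validation machinery exactly, but say nothing about grammar coverage
on real structures -- that is what the hand-decomposed reference library is
for. Passing synthetic tests therefore demonstrates numerical correctness
of the fitting pipeline, not chemical transferability of fitted
contributions to new compound classes.

## Transcription audit

Recounting each table's Molecules column with the ≥3 rule gives
200/165/60/201/109 valid groups for the five tables, while the printed
row A values are 185/154/61/188/108 (and the vaporization narrative
quotes 187). No counting variant reproduces the printed numbers, which
evidently reflect the authors' internal run rather than a recount of the
printed columns. The audit reports both numbers and surfaces every
discrepancy as a data note; nothing is silently reconciled. The packaged
TSVs are guarded by a SHA-256 manifest and refuse to load on mismatch.
Blank printed cells (one row: `O|N2(2pi)` in the fusion-entropy table) are
stored as missing and make any molecule containing the group unpredictable
for that descriptor.

## Known limitations

- The headline training statistics of the original study are not
  reproducible here: its multi-thousand-molecule training sets are not
  packaged. The full pipeline is exercised end-to-end on synthetic data
  instead.
- The H/H Acceptor motif and the angle-group unit are this package's
  documented choices where the source is silent; other readings would
  shift a small number of feature counts.
- Predictions are refused, not extrapolated, outside the valid-group
  vocabulary; coverage therefore tracks the training data's chemical
  diversity (e.g. most boron and many phosphorus environments are
  refused).
- No temperature extrapolation away from 298.15 K, no liquid-crystal
  phase-sequence prediction, no 3D/stereochemical effects.
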