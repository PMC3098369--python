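# Methods

## The model

A chondroitin oligosaccharide CN_n is represented as n rigid pyranose
residues — β-D-GlcA (glucuronate) and β-D-GalNAc (N-acetylgalactosamine,
the galacto C4 epimer) — joined by alternating β(1→3) (GlcA→GalNAc) and
β(1→4) (GalNAc→GlcA) glycosidic bonds, residue 1 at the reducing end.
Conformation is parameterised entirely in torsion space:

* one (φ, ψ) pair per linkage, IUPAC heavy-atom definitions
  (φ₁₋₃ = O5(U)–C1(U)–O1(U)–C3(N), ψ₁₋₃ = C1(U)–O1(U)–C3(N)–C4(N);
  φ₁₋₄ = O5(N)–C1(N)–O1(N)–C4(U), ψ₁₋₄ = C1(N)–O1(N)–C4(U)–C5(U)),
  degrees in (−180, 180], positive clockwise;
* per-GalNAc exocyclic torsions: hydroxymethyl ω (O5–C5–C6–O6) and the
  acetamido rotation (H2–C2–N–HN), both defaulting to trans, consistent
  with the observed ~9–10 Hz ³J(HN,H2) couplings.

Template geometry is idealised: uniform ring bonds of 1.50 Å, a chair whose
six ring torsions alternate exactly ±60° (the ideal ⁴C₁, comfortably inside
the ±(60 ± 20)° restraint window), exocyclic bonds C–C 1.52 Å, C–O 1.43 Å,
C1–O1 1.41 Å, C–H 1.09 Å, and tetrahedral substituent slots.  The ring
chirality (the sign phase of the torsion alternation) is fixed to the
D-series; it was validated operationally — only this enantiomer reproduces
the short trans-glycosidic H3(N)–H1(U)/H1(N)–H4(U) contacts (2.2–2.3 Å) and
medium HN(N)–H1(U) contacts (~3.1 Å) at the published torsion values, and
the gauche H3–C3–C4–H4 / H4–C4–C5–H5 pattern that distinguishes GalNAc from
the all-trans GlcA.  Chains are assembled by natural-extension placement:
the glycosidic oxygen takes the acceptor's pruned hydroxyl position, C1 and
O5 of the donor are placed by the requested ψ and φ, and the rigid residue
follows by an exact three-point frame map, so set-then-measure round-trips
are exact to floating-point precision (tested at 10⁻⁶°).

## NOE calibration and restraints

The spin-pair model I = k·r⁻⁶ is fitted through the origin (the physical
model has no intercept): k = Σ xᵢIᵢ / Σ xᵢ², x = r⁻⁶, over five
intra-residue 1,3-diaxial reference contacts whose distances are fixed by
ring geometry.  r⁻⁶ compresses intensity error sixfold, which is why 20%
multiplicative intensity noise yields a median distance error below 4%
(property-tested over 1000 replicates).  Overlapped peaks (the chemically
equivalent linkage contacts of CN₆, multiplicity 3 for β(1→3) and 2 for
β(1→4)) are divided by their multiplicity before inversion — division is
the only direction consistent with per-linkage distances.  Calibrated
distances are binned: r < 2.75 Å → strong (1.8, 2.7); 2.75 ≤ r ≤ 3.8 →
medium (2.8, 3.8); the 2.75 Å split is the midpoint of the gap between the
bins.  Beyond 3.8 Å no restraint is emitted (warning).  Force constant:
10 kcal/mol/Å².

## Annealing potential and protocol

The search potential is the sum of three non-negative terms:

| term | form | constants |
| --- | --- | --- |
| NOE restraints | flat-bottom, k·max(0, d−u)² + k·max(0, l−d)² | k = 10 kcal/mol/Å² |
| ring pucker | flat-bottom on each ring torsion, zero inside ±(60 ± 20)° | 100 kcal/mol/rad² |
| sterics | soft sphere k_s(c−d)² for heavy-atom pairs >3 bonds apart, d < c | k_s = 5 kcal/mol/Å², c = 3.0 Å |

Rings being rigid, the pucker term is identically zero along the search
path; it is evaluated so arbitrary coordinates (e.g. parsed files) can be
scored.  This potential deliberately replaces an all-atom force field with
generalized-Born solvent: the aim is a conformational search driven by the
published restraints and force constants, not absolute energetics — so
absolute φ/ψ basin positions and the ensemble RMSD spread are reported for
inspection, never asserted.

One round is a Metropolis walk over the torsion vector under a linear
heat (1 K → 500 K) / hold (500 K) / cool (→ 0 K) schedule — 80/80/120 steps
of 6 single-torsion moves each at these desk-scale problem sizes — with
Gaussian proposals whose width scales with temperature (σ = 30° at 500 K
down to 2° near 0 K) and kT = 0.0019872·T kcal/mol.  At T = 0 only downhill
moves are accepted.  Each round ends with a derivative-free Powell quench
(≤2000 evaluations) standing in for gradient minimisation; because the
restraint wells are flat-bottomed and mutually satisfiable, quenched rounds
generically reach zero restraint energy (max violation 0, well under the
0.03 Å bound).  The production protocol runs 250 rounds from seeds
seed+0…seed+249, ranks by energy (ties broken by seed index) and keeps
round(0.10 × n) conformers.  Fixing the seed fixes the entire ensemble
bit-for-bit.

## Coupling back-calculation

Ring ³J(H,H) uses the generalized substituent-corrected Karplus equation
J(θ) = P₁cos²θ + P₂cosθ + P₃ + Σᵢ Δχᵢ[P₄ + P₅cos²(ξᵢθ + P₆|Δχᵢ|)].
Coefficients ship in an editable YAML registry (three- and four-substituent
parameter sets; Huggins electronegativity differences O 1.3, N 0.85,
C 0.4); β-substituent group corrections are not applied.  Substituent
orientation signs ξᵢ are derived from the model's own geometry: for a
substituent S on the carbon bearing proton H, ξ is the sign of the wrapped
offset between the S-path torsion and the proton torsion (S sits near
θ ± 120°).  The exact substituent assignments used historically for these
sugars are not documented, so calculated values are compared to
observations as a report (per-pair Δ and RMS), never against a threshold.
The acetamido ³J(HN,H2) uses a plain A·cos²θ + B·cosθ + C form; the shipped
defaults (A = 9.0, B = −1.1, C = 0.4 Hz) are an approximate
parameterisation chosen to give the ~10.5 Hz trans plateau typical of
N-acetyl amino sugars and are configuration, not code — the function
refuses to run without coefficients.

## Ensemble analytics

* RMSD: optimal rigid superposition (quaternion/Kabsch via
  `scipy.spatial.transform.Rotation.align_vectors`), default selection
  heavy atoms + polar hydrogens ("all-atom" in the carbohydrate-NMR sense);
  selectable.
* Torsion statistics: circular mean by unit-vector averaging and circular
  std √(−2 ln R̄), which coincides with the linear std for the tight (<10°)
  dispersions of a restrained ensemble.
* Hydrogen bonds: geometric criteria H···A ≤ 2.5 Å and D–H···A ≥ 120°
  (conventional cutoffs; only distances are published for the reference
  analysis), donors O–H/N–H, acceptors N/O, sorted by distance.
* Literature comparison: circular absolute differences, so −170° vs 170°
  is 20°, not 340°.
* Temperature coefficients: OLS slope of δ(T) × 1000 (ppb/°C) with R²;
  |Δδ/ΔT| > 3 ppb/°C (open interval) classifies an amide as lacking a
  persistent intramolecular hydrogen bond, and the distance to the
  free-exchange reference (−11 ppb/°C) is reported alongside.

## Synthetic data: what it does and does not emulate

The generators invert the exact models the pipeline assumes: NOESY
intensities are k·r⁻⁶ of a known structure (optional multiplicative
log-normal noise, mean-one; fractional sd as given), overlap grouping sums
the equivalent-linkage peaks at 3:2 multiplicity, and shift series are
linear in temperature with Gaussian noise.  The reference CN₆ fixture is
built at the ensemble-average glycosidic torsions of the published analysis
and is clearly a synthetic stand-in for the deposited coordinates — tests
that need the true deposition are gated on a locally provided file.
Consequently, green tests demonstrate internal consistency (the pipeline
inverts its own generative model, the restraints are satisfiable, the
estimators are exact on their asymptotic forms) — they do not demonstrate
robustness to spin diffusion, mixing-time effects, peak-picking error or
assignment ambiguity, none of which the generators model.

## Numerical choices and edge cases

* Torsions wrap to (−180, 180], with −180 mapped to +180.
* Degenerate dihedrals (coincident or collinear defining points) raise a
  dedicated error rather than returning NaN.
* The through-origin calibration is exact for a single reference point;
  empty reference lists and non-positive intensities/distances are
  rejected.
* bin boundary: exactly 2.75 Å goes medium (r < 2.75 is strong); exactly
  ±3.0 ppb/°C classifies as hydrogen-bond-consistent (closed interval).
* Clashes after chain placement (non-bonded heavy atoms < 1.5 Å) are
  reported via a warning and recorded on the model, not silently accepted.
* Multi-model PDB reading validates MODEL/ENDMDL pairing first (errors name
  the offending model), maps deposited residue names through an overridable
  alias table, and aliases acceptor-side glycosidic oxygens (O3/O4) to the
  donor's O1 when needed so torsion quadruples resolve on deposited files.

## Problem sizes

The shipped defaults — 250 annealing rounds of 280 schedule steps × 6
moves plus quench on the hexasaccharide (16 torsional degrees of freedom,
132 atoms) — are the package's production protocol and complete in a few
minutes on one core; Monte-Carlo property checks use 300–1000 replicates.

## Known limitations

* Single-conformer coupling back-calculation (no ensemble averaging), as in
  the reference analysis.
* No relaxation-matrix treatment of spin diffusion; intensities are assumed
  isolated-spin-pair.
* The simplified potential does not reproduce force-field energetics;
  ensemble spread and basin positions are qualitative.
* Ring flexibility (boats, skew-boats) and alternative ω rotamer
  populations are outside the model by construction.
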