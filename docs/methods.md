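# Methods

## The binding model

The package's kinetic core is reversible bimolecular association,
E + B ⇌ C, starting from equal free concentrations [E]₀ = [B]₀ and no
complex. Mass action gives

    d[E]/dt = −k₁[E]² + k₋₁([E]₀ − [E]).

The right-hand side factors over its roots r₊ = k − a and
r₋ = −(k + a), where a = k₋₁/2k₁ and k = √(k₋₁² + 4k₁k₋₁[E]₀)/2k₁, so
the solution is a ratio of exponentials in q = exp(−2k₁kt):

    [E](t) = (r₊([E]₀ − r₋) − r₋([E]₀ − r₊)q) / (([E]₀ − r₋) − ([E]₀ − r₊)q).

Using the identity k² − a² = 2a[E]₀ this is algebraically identical to
the equivalent arrangement

    [E](t) = [E]₀((a + k) + (k − a)q) / (([E]₀ + a + k) − ([E]₀ + a − k)q);

both arrangements are implemented (`free_concentration`,
`free_concentration_printed`) and tested for pointwise equality to
1 × 10⁻¹², and both are cross-checked against direct stiff-safe
numerical integration of the ODE (Radau, rtol 1 × 10⁻¹⁰) to better than
1 × 10⁻⁸ over ten relaxation times.

Properties: [E](0) = [E]₀ exactly; [E](t) decreases monotonically to
the equilibrium root r₊ of k₁x² + k₋₁x − k₋₁[E]₀ = 0; for k₋₁ = 0 the
general form is 0/0, so the irreversible limit [E]₀/(1 + k₁[E]₀t) is
evaluated analytically, and the general form converges to it pointwise
as k₋₁ → 0 (verified at k₋₁ = 1 × 10⁻¹⁰ to 1 × 10⁻⁶).

Rate constants are deliberately unitless. Ensembles from coarse-grained
simulation carry a distorted internal clock, so only ratios are
transferable; the convention [E]₀ = 1 makes [E](t) an unbound fraction
and K_D = k₋₁/k₁ a dimensionless affinity.

### Fitting

`fit_second_order_kinetics` minimizes squared residuals of the closed
form over (log k₁, log k₋₁) with [E]₀ fixed (default 1), using
Levenberg–Marquardt. Logs make positivity structural. The starting
point takes k₁ from the initial slope (−d[E]/dt|₀/[E]₀²) and k₋₁ from
the plateau through the equilibrium quadratic. The RSS surface has a
flat ridge (k₋₁ → ∞ drives the model to the constant [E]₀), so the
informed start is always backed by eight log-spaced k₁ starts and the
lowest-RSS solution wins; non-convergence is flagged on the result.
Standard errors come from the Gauss–Newton covariance, delta-method
transformed back to the natural scale. Degenerate inputs (fewer than
5 points, zero variance) are rejected rather than fitted.

## Trajectory state assignment

Pose ensembles are ligand coordinates after the receptor frame has been
fixed (`superpose_kabsch`, a thin wrapper over a least-squares proper
rotation with the RMSD recomputed from coordinates to avoid
cancellation near zero). Per-frame RMSD to the reference pose feeds two
steps:

* **Clustering** — hierarchical agglomerative (average linkage by
  default, single available) on the pairwise ligand-RMSD matrix, cut at
  a user threshold. Cluster ids are relabeled by first frame
  occurrence, making the partition deterministic and
  permutation-invariant up to renaming. The native-like cluster is the
  one with minimal mean RMSD to the reference; ties resolve toward
  larger occupancy, then smaller id.
* **Bound cutoff** — mean RMSD-to-reference of the native-like cluster
  plus its maximum within-cluster distance. "Maximum distance of the
  within-cluster family" is taken as the maximum *pairwise* RMSD inside
  the cluster (distance-to-medoid was the alternative; pairwise needs
  no extra definition of a center and upper-bounds it). A singleton
  native cluster contributes zero width, by definition rather than
  error. Frames with RMSD ≤ cutoff are bound — the boundary belongs to
  the bound ("proper quaternary structure") state.

Replica ensembles are sampled on a time grid using the most recent
frame at or before each grid time; the unbound fraction is then the
per-time mean of unbound replicas, which by construction lies in [0, 1]
and complements the bound fraction exactly.

## Stochastic generators and study conditions

`simulate_binding_gillespie` has two regimes because the mapping from
an ensemble of simulation boxes to a second-order rate law is genuinely
ambiguous:

* **Well-mixed** (default): exact stochastic simulation of E + B ⇌ C
  among n molecules of each species, association propensity
  k₁·nE·nB/n, dissociation propensity k₋₁·nC. The divisor n makes
  counts/n a concentration on the [E]₀ = 1 scale, so the ensemble mean
  follows the closed form above; this regime backs the
  parameter-recovery studies.
* **Single-pair**: independent two-state telegraph replicas
  (association rate k₁[E]₀, dissociation rate k₋₁), emulating many
  boxes that each hold one receptor–ligand pair. Its mean is
  first-order, not second-order; it exists to make the distinction
  testable, not to fit.

Recovery-study conditions, fixed once from the kinetics: rates
(k₁, k₋₁) = (5.594, 0.00105), n = 10⁴ molecules, 20 seeds, grid step
0.05, horizon t_end = 60 ≈ 9 relaxation times 1/(2k₁k) ≈ 6.5, which
covers both the second-order decay and a long plateau (the plateau is
what identifies k₋₁). At these conditions the median relative
recovery error is well under 10% for both constants.

The pose-cloud generator plants clusters by displacing the reference by
a random translation of exactly the requested RMSD (a uniform
translation of norm d shifts RMSD by exactly d) plus per-frame Gaussian
jitter, and scatters decoys at norms uniform in [shell, shell + 5] Å.
Planted labels ride along so every downstream statistic can be
recomputed independently of the clustering code.

The toy two-chain complex is a synthetic geometric scaffold, not a
physical structure: residues (N, CA, C, O, CB at fixed offsets) sit on
a 10 Å grid; designed contact pairs are brought to a closest heavy-atom
distance of 3.6 Å while every other inter-chain pair stays beyond 6 Å,
so the contact pattern at any cutoff in [4.0, 5.0] Å is knowable by
construction; SG atoms of designated cysteine pairs are planted exactly
2.04 Å apart (covalent S–S ≈ 2.05 Å) in an off-interface pocket.
Passing tests on these fixtures demonstrate bookkeeping correctness —
exact contact counting, ranking, greedy SG matching — not geometric
realism of real interfaces (no side-chain packing, occupancy/altloc
variety, or near-cutoff ambiguity beyond what the random layouts
produce).

## Interface analysis choices

The contact criterion is heavy-atom pairs within a configurable cutoff,
default 4.5 Å with a 4.0/4.5/5.0 Å calibration grid exposed — interface
definitions in the literature vary and the count map itself is the
primary object. Counts are stored as raw atom-pair integers (binary
residue contacts are derivable; the reverse is not). Grayscale export
normalizes by the matrix maximum (black = max) into plain-text PGM.
Author residue numbering is preserved everywhere; hydrogens are
excluded; for altlocs the highest-occupancy conformer is kept (ties →
'A'). Disulfide detection uses an SG–SG cutoff of 2.5 Å (bond length
plus slack) with greedy ascending-distance matching so each SG joins at
most one bridge.

## SPR model

Association R(t) = C·k_a·R_max/(C·k_a + k_d)·(1 − e^(−(C·k_a + k_d)t)),
dissociation R(t′) = R_stop·e^(−k_d t′). The global fit shares one
(k_a, k_d, R_max) across all concentrations — with a single curve k_a
and R_max trade off, so single-concentration fits are flagged rather
than refused. Default simulation conditions mirror a standard
streptavidin-chip run: R_max 1100 RU, injections of 240 s at 30 µL/min,
600 s dissociation, 1 s sampling, concentrations 1–15 µM, Gaussian
noise 2 RU for the noisy studies. Mass transport, drift and bulk
refractive-index steps are not modeled; curves are assumed
reference-subtracted upstream. Fits are validated by round-trip
recovery (exact on noiseless input, median error under 5% at 2 RU
noise), not against any external instrument record.

## NOE bookkeeping

Sequence-separation classes follow the standard NMR convention: 0
intra-residue, 1 sequential, 2–4 medium-range, ≥ 5 long-range (the
class names are conventional; the boundaries are the package's stated
definition). Proton names are normalized so NH ≡ HN and branch indices
are stripped (Hβ2 → Hβ). Disulfide connectivity accepts Hβ–Hβ, HN–Hα
and HN–Hβ patterns between two cysteines; each cysteine joins at most
one bridge, assigned greedily by support count with ties toward the
smaller residue pair. The summary operation counts what it is given —
it takes no position on upstream peak-overlap exclusions.

## Known limitations

* The closed-form model assumes equal initial concentrations of the two
  partners and a single binding mode; competition, cooperativity and
  unequal stoichiometry are out of scope.
* Clustering statistics depend on the chosen threshold and linkage;
  cluster probabilities from replica-exchange ensembles additionally
  depend on thermodynamic reweighting, which this package deliberately
  does not do.
* The single-pair regime's ensemble mean does not follow the
  second-order closed form; fitting it anyway estimates an effective,
  not mechanistic, k₁.
* PDB support covers fixed-column ATOM/HETATM records (via biotite);
  mmCIF is out of scope.
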