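# pepbind

Tools for designing and kinetically evaluating peptide inhibitors of
protein–protein interfaces, built around the BTLA/HVEM immune-checkpoint
complex as the motivating system. BTLA is an inhibitory receptor on
T cells; its ligand HVEM binds through the first cysteine-rich domain
(CRD1), and a disulfide-stabilized fragment of that domain can compete
with the full protein for the receptor. Quantifying whether such a
peptide is a viable inhibitor takes four kinds of analysis, all provided
here as a tested library plus a thin CLI:

1. **Interface mapping** (`pepbind.structure`) — parse a two-chain
   complex from PDB text, count inter-chain heavy-atom contacts per
   residue pair at a distance cutoff (the grayscale contact-map matrix),
   rank hot-spot residues by contact count, extract a candidate fragment
   with point substitutions, and detect disulfide bridges from SG–SG
   geometry.
2. **Trajectory state assignment** (`pepbind.poses`) — superpose pose
   ensembles (Kabsch), cluster them on pairwise RMSD, derive the
   bound-state cutoff as *mean RMSD of the most native-like cluster +
   its maximum within-cluster distance*, and convert replica ensembles
   into an unbound-fraction time series.
3. **Binding kinetics** (`pepbind.kinetics`) — the closed-form solution
   of second-order reversible binding,

   d[E]/dt = −k₁[E]² + k₋₁([E]₀ − [E]),

   [E](t) = [E]₀ · [(a + k) + (k − a)e^(−2k₁kt)] / [([E]₀ + a + k) − ([E]₀ + a − k)e^(−2k₁kt)],

   with a = k₋₁/2k₁ and k = √(k₋₁² + 4k₁k₋₁[E]₀)/2k₁, fitted to
   unbound-fraction series by nonlinear least squares; K_D = k₋₁/k₁ and
   affinity ratios follow.
4. **SPR analysis** (`pepbind.spr`) — simulation and global fitting of
   1:1 Langmuir sensorgrams, dR/dt = k_a·C·(R_max − R) − k_d·R, one
   (k_a, k_d, R_max) shared across all analyte concentrations.
5. **NOE bookkeeping** (`pepbind.restraints`) — classify distance
   restraints by sequence separation (intra / sequential / medium /
   long) and infer disulfide connectivity from Cys–Cys NOE crosspeak
   patterns (Hβ–Hβ, HN–Hα, HN–Hβ).

Everything is testable offline: `pepbind.synthetic` generates stochastic
binding trajectories (exact Gillespie simulation with known rate
constants), pose clouds with planted clusters, noisy sensorgrams, and
miniature two-chain complexes with designed contacts and disulfides.

## Worked example

```python
import numpy as np
from pepbind import kinetics as kin, structure, synthetic

# design stage: toy complex standing in for a receptor/ligand crystal
pdb_text, truth = synthetic.generate_toy_complex(seed=7)
model = structure.parse_structure(pdb_text)
cmap = structure.compute_contact_map(model, "A", "B", cutoff_angstrom=4.5)
ranking = structure.rank_interface_residues(cmap, side="ligand")
print("interface residues on chain B:", [(r[1], t) for r, t in ranking.entries])
print("disulfides:", structure.detect_disulfides(model))
frag = structure.extract_fragment(model, "B", 14, 39, substitutions=[(15, "C", "S")])
print("fragment 14-39:", frag.sequence)

# kinetics stage: stochastic ensemble -> closed-form fit -> K_D
config = synthetic.SimulationConfig(k1=5.594, k_minus1=0.00105, seed=1)
series, _ = synthetic.simulate_binding_gillespie(config)
fit = kin.fit_second_order_kinetics(series)
print(f"k1 = {fit.params.k1:.3f}   k_minus1 = {fit.params.k_minus1:.5f}   "
      f"K_D = {fit.k_d:.3g}")
```

prints

```
interface residues on chain B: [(18, 1), (24, 1), (25, 1), (28, 1), (36, 1)]
disulfides: [(('B', 16), ('B', 29)), (('B', 19), ('B', 37))]
fragment 14-39: ASCAACAAAAAAAAACAAAAAAACAA
k1 = 5.647   k_minus1 = 0.00107   K_D = 0.000189
```

The five ranked chain-B residues are exactly the contacts the generator
designed; the two SG–SG bridges are the planted (16, 29) and (19, 37)
topology; the fragment sequence shows the Cys15→Ser substitution at its
second position. The fitted rate constants recover the generating values
(k₁ = 5.594, k₋₁ = 0.00105) to about 1% and 2% from a single stochastic
ensemble of 10⁴ molecule pairs, giving K_D ≈ 1.9 × 10⁻⁴ in the unitless
convention where [E]₀ = 1.

The same operations are available from the shell, e.g.

```sh
pepbind simulate --k1 5.594 --kminus1 0.00105 --seed 1 --out unbound.tsv
pepbind fitkin --series unbound.tsv --report fit.json
pepbind contacts --pdb complex.pdb --chain-a A --chain-b B --cutoff 4.5 \
    --out-map map.tsv --out-rank rank.tsv
```

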