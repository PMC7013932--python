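"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without downloads:

* stochastic binding trajectories (exact Gillespie simulation of
  E + B <=> C, or independent single-pair telegraph replicas) whose
  mean obeys the closed-form second-order kinetics;
* pose clouds with planted clusters at chosen RMSD offsets plus uniform
  decoys, with the planted labels returned alongside;
* a miniature two-chain complex written as PDB text whose inter-chain
  contacts and SG-SG bridge geometry are designed exactly, with the
  ground-truth tables returned.

All generators are deterministic given (configuration, seed).

The toy complex is a synthetic geometric scaffold: residues are placed
on a regular grid so that designed pairs sit within 4.0 A and every
other inter-chain pair sits beyond 6.0 A; it is a stand-in with exact
bookkeeping, not a physical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ConcentrationSeries, KineticsParams
from .poses import PoseEnsemble, StateSeries

__all__ = [
    "SimulationConfig",
    "simulate_binding_gillespie",
    "generate_pose_cloud",
    "generate_toy_complex",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one stochastic binding simulation."""

    k1: float
    k_minus1: float
    E0: float = 1.0
    n_molecules: int = 10_000
    n_replicas: int = 100
    t_end: float = 60.0
    grid_step: float = 0.05
    seed: int = 0
    mode: str = "wellmixed"  # or "singlepair"

    def __post_init__(self) -> None:
        KineticsParams(max(self.k1, 1e-300), self.k_minus1, self.E0)  # validate signs
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.t_end <= 0 or self.grid_step <= 0:
            raise ValueError("t_end and grid_step must be positive")
        if self.mode not in ("wellmixed", "singlepair"):
            raise ValueError("mode must be 'wellmixed' or 'singlepair'")
        n = self.n_molecules if self.mode == "wellmixed" else self.n_replicas
        if n < 1:
            raise ValueError("need at least one molecule/replica")


def _grid(config: SimulationConfig) -> np.ndarray:
    return np.arange(0.0, config.t_end + config.grid_step / 2, config.grid_step)


def simulate_binding_gillespie(
    config: SimulationConfig,
) -> tuple[ConcentrationSeries, list[StateSeries]]:
    """Exact stochastic simulation of reversible binding.

    Well-mixed mode: E + B -> C with propensity ``k1 nE nB / n_molecules``
    and C -> E + B with propensity ``k_minus1 nC``, starting from
    ``nE = nB = n_molecules``, ``nC = 0``; the divisor makes concentrations
    fractions so the rates match the unitless ``KineticsParams`` and the
    ensemble mean follows the closed-form model.  Returns the sampled
    unbound fraction ``nE / n_molecules`` and an empty replica list.

    Single-pair mode: ``n_replicas`` independent two-state telegraph
    processes with association rate ``k1 E0`` and dissociation rate
    ``k_minus1``; returns the ensemble unbound fraction and the
    per-replica state series.
    """
    rng = np.random.default_rng(config.seed)
    grid = _grid(config)
    if config.mode == "wellmixed":
        return _simulate_wellmixed(config, rng, grid), []
    return _simulate_singlepair(config, rng, grid)


def _simulate_wellmixed(
    config: SimulationConfig, rng: np.random.Generator, grid: np.ndarray
) -> ConcentrationSeries:
    n = config.n_molecules
    n_e = n
    n_c = 0
    t = 0.0
    values = np.empty_like(grid)
    gi = 0
    while True:
        a_on = config.k1 * n_e * n_e / n  # nE == nB at all times
        a_off = config.k_minus1 * n_c
        a_tot = a_on + a_off
        t_next = t + (rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf)
        while gi < len(grid) and grid[gi] < t_next:
            values[gi] = n_e / n
            gi += 1
        if gi >= len(grid) or not np.isfinite(t_next):
            break
        t = t_next
        if rng.random() < a_on / a_tot:
            n_e -= 1
            n_c += 1
        else:
            n_e += 1
            n_c -= 1
    if gi < len(grid):  # absorbed (no events possible): state is frozen
        values[gi:] = n_e / n
    return ConcentrationSeries(grid, values)


def _simulate_singlepair(
    config: SimulationConfig, rng: np.random.Generator, grid: np.ndarray
) -> tuple[ConcentrationSeries, list[StateSeries]]:
    rate_on = config.k1 * config.E0
    rate_off = config.k_minus1
    replicas = []
    n_unbound = np.zeros(len(grid))
    for _ in range(config.n_replicas):
        times = [0.0]
        bound = [False]
        t = 0.0
        state = False
        while t < config.t_end:
            rate = rate_off if state else rate_on
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= config.t_end:
                break
            state = not state
            times.append(t)
            bound.append(state)
        s = StateSeries(
            times=np.array(times),
            bound=np.array(bound, dtype=bool),
            cutoff_angstrom=1.0,
        )
        replicas.append(s)
        idx = np.searchsorted(s.times, grid, side="right") - 1
        n_unbound += ~s.bound[idx]
    series = ConcentrationSeries(grid, n_unbound / config.n_replicas)
    return series, replicas


def generate_pose_cloud(
    reference: np.ndarray,
    cluster_specs: list[tuple[float, float, int]],
    n_decoys: int = 0,
    decoy_shell: float = 15.0,
    seed: int = 0,
) -> PoseEnsemble:
    """Pose ensemble with planted clusters and uniform decoys.

    Each cluster spec is ``(center_rmsd, spread, n_frames)``: the cluster
    center is the reference displaced by a random rigid translation of
    exactly ``center_rmsd`` (a uniform translation of norm d changes RMSD
    by exactly d), and each frame adds isotropic Gaussian jitter of
    standard deviation ``spread`` per coordinate.  Decoys are displaced by
    random directions with norms uniform in ``[decoy_shell,
    decoy_shell + 5]``.  Planted labels (cluster index, -1 for decoys) are
    stored on the ensemble.
    """
    rng = np.random.default_rng(seed)
    reference = np.asarray(reference, dtype=float)
    frames = []
    labels = []
    for ci, (center_rmsd, spread, n_frames) in enumerate(cluster_specs):
        if spread < 0 or center_rmsd < 0 or n_frames < 1:
            raise ValueError("invalid cluster spec")
        center = reference + center_rmsd * _random_unit(rng)
        for _ in range(n_frames):
            jitter = rng.normal(0.0, spread, size=reference.shape) if spread > 0 else 0.0
            frames.append(center + jitter)
            labels.append(ci)
    for _ in range(n_decoys):
        norm = rng.uniform(decoy_shell, decoy_shell + 5.0)
        frames.append(reference + norm * _random_unit(rng))
        labels.append(-1)
    coords = np.stack(frames) if frames else np.empty((0, *reference.shape))
    return PoseEnsemble(
        times=np.arange(len(frames), dtype=float),
        coords=coords,
        reference=reference,
        true_labels=np.array(labels, dtype=int),
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# fixed intra-residue heavy-atom offsets (A) around the residue center
_RESIDUE_OFFSETS = {
    "N": (-1.2, 0.3, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.3, 0.0),
    "O": (1.4, 1.4, 0.0),
    "CB": (0.0, -1.2, 0.5),
}

_CHAIN_SPACING = 10.0  # A between residue centers along x
_CONTACT_GAP = 6.0  # y offset of a designed-contact partner (CB-CB 3.6 A apart)
_FAR_Y = 25.0  # y of non-contacting chain-B residues


def generate_toy_complex(
    n_res_a: int = 30,
    n_res_b: int = 26,
    n_designed_contacts: int = 5,
    disulfide_pairs: tuple[tuple[int, int], ...] = ((16, 29), (19, 37)),
    seed: int = 0,
    start_res_a: int = 1,
    start_res_b: int = 14,
    extra_cysteines_b: tuple[int, ...] = (15,),
):
    """Two-chain poly-Ala/Cys toy complex as PDB text, with ground truth.

    Chain A lies along the x-axis; chain B runs parallel at a distance.
    ``n_designed_contacts`` residue pairs (distinct residues on each
    side, chosen by the seeded RNG) are brought together so their closest
    heavy atoms sit 3.6 A apart; every other inter-chain residue pair
    stays beyond 6.0 A.  Cysteines named in ``disulfide_pairs`` (chain-B
    author numbering) get SG atoms planted exactly 2.04 A apart in an
    off-interface pocket.  Returns ``(pdb_text, truth)`` where ``truth``
    has the designed contact pairs with exact heavy-atom pair counts at
    4.5 A and the planted disulfide list.
    """
    if n_res_a < 1 or n_res_b < 1:
        raise ValueError("chains need at least one residue")
    if n_designed_contacts > min(n_res_a, n_res_b):
        raise ValueError("more designed contacts than residues available")
    rng = np.random.default_rng(seed)
    res_a_numbers = list(range(start_res_a, start_res_a + n_res_a))
    res_b_numbers = list(range(start_res_b, start_res_b + n_res_b))

    cys_b = set(extra_cysteines_b)
    for r1, r2 in disulfide_pairs:
        cys_b.update((r1, r2))
    if not cys_b <= set(res_b_numbers):
        raise ValueError("disulfide/cysteine residues outside chain B numbering")

    contact_a = sorted(rng.choice(n_res_a, size=n_designed_contacts, replace=False))
    contact_b = list(rng.permutation(n_res_b)[:n_designed_contacts])
    designed = {
        (res_a_numbers[ia], res_b_numbers[ib])
        for ia, ib in zip(contact_a, contact_b)
    }
    b_partner = {res_b_numbers[ib]: res_a_numbers[ia] for ia, ib in zip(contact_a, contact_b)}
    a_x = {num: _CHAIN_SPACING * i for i, num in enumerate(res_a_numbers)}

    atoms = []  # (chain, resnum, resname, atomname, element, xyz)

    def add_residue(chain, num, name, center, flip_y):
        for atom_name, (dx, dy, dz) in _RESIDUE_OFFSETS.items():
            if flip_y:
                dy = -dy
            atoms.append(
                (chain, num, name, atom_name, atom_name[0],
                 (center[0] + dx, center[1] + dy, center[2] + dz))
            )

    for num in res_a_numbers:
        # chain A mirrored in y so its CB points toward the interface (+y)
        add_residue("A", num, "ALA", (a_x[num], 0.0, 0.0), flip_y=True)
    for i, num in enumerate(res_b_numbers):
        name = "CYS" if num in cys_b else "ALA"
        if num in b_partner:
            center = (a_x[b_partner[num]], _CONTACT_GAP, 0.0)
        else:
            center = (_CHAIN_SPACING * i, _FAR_Y, 0.0)
        add_residue("B", num, name, center, flip_y=False)

    # planted SG pairs, tucked far from both chains and from each other
    sg_positions = {}
    for pi, (r1, r2) in enumerate(disulfide_pairs):
        base = np.array([12.0 * pi, -30.0, 10.0])
        sg_positions[r1] = base
        sg_positions[r2] = base + np.array([2.04, 0.0, 0.0])
    for num in sorted(cys_b):
        if num in sg_positions:
            pos = sg_positions[num]
        else:  # unpaired cysteine: isolated SG
            pos = np.array([12.0 * len(disulfide_pairs) + 20.0 + 12.0 * num, -30.0, 10.0])
        atoms.append(("B", num, "CYS", "SG", "S", tuple(pos)))

    pdb_text = _to_pdb(atoms)
    truth_counts = _brute_force_contacts(atoms, cutoff=4.5)
    truth = {
        "designed_contacts": sorted(designed),
        "contact_counts": truth_counts,
        "disulfide_pairs": sorted(tuple(sorted(p)) for p in disulfide_pairs),
        "chain_a_residues": res_a_numbers,
        "chain_b_residues": res_b_numbers,
    }
    return pdb_text, truth


def _to_pdb(atoms) -> str:
    lines = []
    serial = 1
    for chain, num, name, atom_name, element, (x, y, z) in atoms:
        lines.append(
            f"ATOM  {serial:5d} {atom_name:<4s} {name:>3s} {chain}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _brute_force_contacts(atoms, cutoff: float) -> dict[tuple[int, int], int]:
    """Exhaustive inter-chain heavy-atom pair enumeration (ground truth)."""
    a_atoms = [(num, np.array(xyz)) for ch, num, _n, _a, el, xyz in atoms
               if ch == "A" and el != "H"]
    b_atoms = [(num, np.array(xyz)) for ch, num, _n, _a, el, xyz in atoms
               if ch == "B" and el != "H"]
    counts: dict[tuple[int, int], int] = {}
    for na, xa in a_atoms:
        for nb, xb in b_atoms:
            if float(np.linalg.norm(xa - xb)) <= cutoff:
                counts[(na, nb)] = counts.get((na, nb), 0) + 1
    return counts
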