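"""Protein-complex interface analysis.

Parses two-chain complexes from PDB text, builds inter-chain residue
contact maps (heavy-atom pairs within a distance cutoff, the classic
grayscale interface matrix), ranks interface hot spots by contact count,
extracts candidate peptide fragments with substitutions, and detects
disulfide bridges from SG-SG geometry.

Residue numbering is always the author numbering of the input file;
nothing is renumbered.  Hydrogens are excluded from contact counting;
for alternate locations the highest-occupancy conformer is kept (ties
resolved toward altloc 'A').
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

__all__ = [
    "StructureModel",
    "ContactMap",
    "HotSpotRanking",
    "PeptideFragment",
    "PDBParseError",
    "parse_structure",
    "compute_contact_map",
    "rank_interface_residues",
    "extract_fragment",
    "detect_disulfides",
]

#: 3-letter -> 1-letter amino acid codes
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed into a structure model."""


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    """Atoms of a (multi-chain) complex for one model of a PDB entry."""

    atoms: list[Atom]
    model: int = 1

    def __post_init__(self) -> None:
        coords = self.coords()
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in structure")
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) records")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float).reshape(
            -1, 3
        )

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def chain_residues(self, chain_id: str) -> list[tuple[int, str]]:
        """Residues of a chain as (number, 3-letter name), in file order."""
        seen: dict[int, str] = {}
        for a in self.chain_atoms(chain_id):
            seen.setdefault(a.residue_number, a.residue_name)
        return list(seen.items())


def parse_structure(pdb_text: str, model_index: int = 1) -> StructureModel:
    """Parse the ATOM records of one model from PDB-format text.

    HETATM records and waters are excluded.  ``model_index`` is 1-based as
    in the file; a missing model raises an error listing what is available.
    """
    _check_coordinate_fields(pdb_text)
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        model_count = pdb.get_model_count()
    except Exception as exc:  # malformed beyond coordinate fields
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if model_count == 0:
        raise PDBParseError("no coordinate models in PDB text")
    if not 1 <= model_index <= model_count:
        raise PDBParseError(
            f"model {model_index} not present; available models: "
            f"{list(range(1, model_count + 1))}"
        )
    arr = pdb.get_structure(
        model=model_index, altloc="occupancy", extra_fields=["occupancy"]
    )
    arr = arr[~arr.hetero]
    arr = arr[~np.isin(arr.res_name, list(_WATER_NAMES))]
    atoms = [
        Atom(
            chain_id=str(arr.chain_id[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            x=float(arr.coord[i, 0]),
            y=float(arr.coord[i, 1]),
            z=float(arr.coord[i, 2]),
        )
        for i in range(arr.array_length())
    ]
    return StructureModel(atoms=atoms, model=model_index)


def _check_coordinate_fields(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldval = line[lo:hi].strip()
                try:
                    float(fieldval)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: non-numeric {name} coordinate "
                        f"field {fieldval!r}"
                    ) from None


@dataclass
class ContactMap:
    """Inter-chain residue-by-residue heavy-atom contact counts."""

    receptor_residues: list[tuple[str, int, str]]
    ligand_residues: list[tuple[str, int, str]]
    counts: np.ndarray
    cutoff_angstrom: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (
            len(self.receptor_residues),
            len(self.ligand_residues),
        ):
            raise ValueError("counts shape does not match residue lists")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    def transpose(self) -> "ContactMap":
        """Swap receptor/ligand roles."""
        return ContactMap(
            receptor_residues=list(self.ligand_residues),
            ligand_residues=list(self.receptor_residues),
            counts=self.counts.T.copy(),
            cutoff_angstrom=self.cutoff_angstrom,
        )

    def to_tsv(self, path) -> None:
        labels = lambda res: [f"{c}:{n}:{r}" for c, n, r in res]
        pd.DataFrame(
            self.counts,
            index=labels(self.receptor_residues),
            columns=labels(self.ligand_residues),
        ).to_csv(path, sep="\t")

    def to_pgm(self, path) -> None:
        """Plain-text PGM grayscale: black = maximum count, white = zero."""
        maxc = int(self.counts.max()) if self.counts.size else 0
        if maxc == 0:
            img = np.full(self.counts.shape, 255, dtype=int)
        else:
            img = 255 - (self.counts * 255) // maxc
        h, w = img.shape
        lines = [f"P2", f"{w} {h}", "255"]
        lines += [" ".join(str(v) for v in row) for row in img]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def compute_contact_map(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff_angstrom: float = 4.5,
) -> ContactMap:
    """Count heavy-atom pairs within ``cutoff_angstrom`` between every
    residue of ``chain_a`` (rows) and every residue of ``chain_b`` (cols).

    Residues with no contacts keep their all-zero rows/columns so the map
    spans the full chains.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    available = model.chains()
    for ch in (chain_a, chain_b):
        if ch not in available:
            raise KeyError(f"chain {ch!r} not found; available chains: {available}")

    def heavy(chain):
        return [a for a in model.chain_atoms(chain) if a.element.upper() != "H"]

    atoms_a, atoms_b = heavy(chain_a), heavy(chain_b)
    res_a = model.chain_residues(chain_a)
    res_b = model.chain_residues(chain_b)
    idx_a = {num: i for i, (num, _) in enumerate(res_a)}
    idx_b = {num: j for j, (num, _) in enumerate(res_b)}
    counts = np.zeros((len(res_a), len(res_b)), dtype=int)
    if atoms_a and atoms_b:
        xa = np.array([[a.x, a.y, a.z] for a in atoms_a])
        xb = np.array([[a.x, a.y, a.z] for a in atoms_b])
        within = cdist(xa, xb) <= cutoff_angstrom
        ia, ib = np.nonzero(within)
        for i, j in zip(ia, ib):
            counts[idx_a[atoms_a[i].residue_number], idx_b[atoms_b[j].residue_number]] += 1
    return ContactMap(
        receptor_residues=[(chain_a, num, name) for num, name in res_a],
        ligand_residues=[(chain_b, num, name) for num, name in res_b],
        counts=counts,
        cutoff_angstrom=cutoff_angstrom,
    )


@dataclass
class HotSpotRanking:
    """Interface residues ranked by total inter-chain contact count."""

    entries: list[tuple[tuple[str, int, str], int]]

    def residues(self) -> list[tuple[str, int, str]]:
        return [res for res, _ in self.entries]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(f"{c}:{n}:{r}", total) for (c, n, r), total in self.entries],
            columns=["residue", "total_contacts"],
        ).to_csv(path, sep="\t", index=False)


def rank_interface_residues(cmap: ContactMap, side: str = "ligand") -> HotSpotRanking:
    """Rank one side's residues by marginal contact totals, descending;
    ties broken by ascending residue number; zero-contact residues dropped."""
    if side == "receptor":
        residues, totals = cmap.receptor_residues, cmap.counts.sum(axis=1)
    elif side == "ligand":
        residues, totals = cmap.ligand_residues, cmap.counts.sum(axis=0)
    else:
        raise ValueError("side must be 'receptor' or 'ligand'")
    entries = [
        (res, int(tot))
        for res, tot in zip(residues, totals)
        if tot > 0
    ]
    entries.sort(key=lambda e: (-e[1], e[0][1]))
    return HotSpotRanking(entries=entries)


@dataclass
class PeptideFragment:
    """A contiguous chain fragment chosen as a candidate inhibitor."""

    source_chain: str
    start_residue: int
    end_residue: int
    sequence: str
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.end_residue - self.start_residue + 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"sequence length {len(self.sequence)} != residue span {expected}"
            )
        for pos, _from, _to in self.substitutions:
            if not self.start_residue <= pos <= self.end_residue:
                raise ValueError(f"substitution position {pos} outside fragment")
        for r1, r2 in self.disulfide_pairs:
            for r in (r1, r2):
                if self.sequence[r - self.start_residue] != "C":
                    raise ValueError(f"disulfide partner {r} is not a cysteine")

    def letter_at(self, residue_number: int) -> str:
        return self.sequence[residue_number - self.start_residue]


def extract_fragment(
    model: StructureModel,
    chain: str,
    start: int,
    end: int,
    substitutions: list[tuple[int, str, str]] | None = None,
    disulfide_pairs: list[tuple[int, int]] | None = None,
) -> PeptideFragment:
    """Read the 1-letter sequence of residues ``start..end`` (inclusive,
    author numbering) of a chain and apply point substitutions.

    A gap inside the range is an error listing the missing numbers.
    """
    substitutions = list(substitutions or [])
    residues = dict(model.chain_residues(chain))
    wanted = range(start, end + 1)
    missing = [n for n in wanted if n not in residues]
    if missing:
        raise KeyError(f"chain {chain!r} is missing residues {missing} in [{start}, {end}]")
    letters = []
    for n in wanted:
        name = residues[n]
        if name not in AA_3TO1:
            raise ValueError(f"residue {n} has non-standard name {name!r}")
        letters.append(AA_3TO1[name])
    for pos, aa_from, aa_to in substitutions:
        if not start <= pos <= end:
            raise ValueError(f"substitution position {pos} outside [{start}, {end}]")
        current = letters[pos - start]
        if current != aa_from:
            raise ValueError(
                f"substitution at {pos} expects {aa_from!r} but chain has {current!r}"
            )
        letters[pos - start] = aa_to
    return PeptideFragment(
        source_chain=chain,
        start_residue=start,
        end_residue=end,
        sequence="".join(letters),
        substitutions=substitutions,
        disulfide_pairs=list(disulfide_pairs or []),
    )


def detect_disulfides(
    model: StructureModel, sg_cutoff_angstrom: float = 2.5
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Detect disulfide bridges as CYS SG-SG pairs within the cutoff.

    Each SG participates in at most one reported bridge; candidate pairs
    are accepted greedily by ascending SG-SG distance (a covalent S-S bond
    is ~2.05 A, so the default 2.5 A leaves slack but excludes mere
    proximity).
    """
    if sg_cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    sgs = [
        a
        for a in model.atoms
        if a.residue_name == "CYS" and a.atom_name == "SG"
    ]
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(
                np.linalg.norm(
                    np.array([sgs[i].x, sgs[i].y, sgs[i].z])
                    - np.array([sgs[j].x, sgs[j].y, sgs[j].z])
                )
            )
            if d <= sg_cutoff_angstrom:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for _d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        key_i = (sgs[i].chain_id, sgs[i].residue_number)
        key_j = (sgs[j].chain_id, sgs[j].residue_number)
        pairs.append(tuple(sorted((key_i, key_j))))
    return sorted(pairs)
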