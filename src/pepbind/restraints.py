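"""NOE distance-restraint bookkeeping.

Restraints are upper bounds on proton-proton distances read off a NOESY
spectrum.  They are classified by sequence separation |i - j| using the
standard convention: intra-residue (0), sequential (1), medium-range
(2-4), long-range (>= 5).  Cysteine-cysteine NOE patterns
(Hb-Hb, HN-Ha, HN-Hb) additionally support disulfide-connectivity
assignment: an S-S bond holds the two side chains close enough for these
crosspeaks to appear.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DistanceRestraint",
    "RestraintSummary",
    "classify_restraint",
    "summarize_restraints",
    "infer_disulfide_connectivity",
    "read_restraints_tsv",
    "read_restraints_upl",
]

CLASSES = ("intra", "sequential", "medium", "long")


@dataclass(frozen=True)
class DistanceRestraint:
    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    upper_bound: float  # Angstrom

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")
        if self.residue_i <= 0 or self.residue_j <= 0:
            raise ValueError("residue numbers must be positive")


@dataclass
class RestraintSummary:
    intra: int
    sequential: int
    medium: int
    long: int

    @property
    def total(self) -> int:
        return self.intra + self.sequential + self.medium + self.long


def classify_restraint(r: DistanceRestraint) -> str:
    """Class label by sequence separation: 0 intra, 1 sequential,
    2-4 medium, >=5 long.  Symmetric in (i, j)."""
    sep = abs(r.residue_i - r.residue_j)
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


def summarize_restraints(restraints: list[DistanceRestraint]) -> RestraintSummary:
    """Per-class counts; order-invariant."""
    tally = Counter(classify_restraint(r) for r in restraints)
    return RestraintSummary(*(tally.get(c, 0) for c in CLASSES))


def _proton_base(atom: str) -> str:
    """Normalize a proton name: NH == HN; strip branch digits (HB2 -> HB)."""
    a = atom.upper().replace("β", "B").replace("α", "A")
    if a == "NH":
        a = "HN"
    return a.rstrip("123")


# unordered proton-name pairs that evidence an S-S bridge between two Cys
_DISULFIDE_PATTERNS = {
    frozenset(("HB", "HB")),
    frozenset(("HN", "HA")),
    frozenset(("HN", "HB")),
}


def infer_disulfide_connectivity(
    noe_contacts: list[tuple[int, str, int, str]],
    cysteines: list[int],
) -> list[tuple[int, int]]:
    """Candidate disulfide pairs from Cys-Cys NOE contacts.

    A pair is supported by any contact between the two cysteines matching
    an Hb-Hb, HN-Ha or HN-Hb pattern.  Each cysteine joins at most one
    pair; pairs are accepted greedily by descending number of supporting
    contacts, ties toward the smaller residue pair.  Deterministic and
    independent of contact order.
    """
    if not cysteines:
        raise ValueError("cysteine list must be non-empty")
    cys = set(cysteines)
    support: Counter[tuple[int, int]] = Counter()
    for res_i, atom_i, res_j, atom_j in noe_contacts:
        if res_i == res_j or res_i not in cys or res_j not in cys:
            continue
        pattern = frozenset((_proton_base(atom_i), _proton_base(atom_j)))
        if pattern in _DISULFIDE_PATTERNS:
            support[tuple(sorted((res_i, res_j)))] += 1
    used: set[int] = set()
    pairs = []
    for pair, _count in sorted(support.items(), key=lambda kv: (-kv[1], kv[0])):
        if pair[0] in used or pair[1] in used:
            continue
        used.update(pair)
        pairs.append(pair)
    return sorted(pairs)


def read_restraints_tsv(path) -> list[DistanceRestraint]:
    """5-column TSV: residue_i, atom_i, residue_j, atom_j, upper_bound."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DistanceRestraint(
            int(row.iloc[0]), str(row.iloc[1]), int(row.iloc[2]), str(row.iloc[3]),
            float(row.iloc[4]),
        )
        for _, row in df.iterrows()
    ]


def read_restraints_upl(path) -> list[DistanceRestraint]:
    """CYANA .upl layout: resnum resname atom resnum resname atom distance.

    Atom names pass through untouched apart from whitespace.
    """
    restraints = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 7:
                raise ValueError(f"malformed .upl line: {line.rstrip()!r}")
            restraints.append(
                DistanceRestraint(
                    int(parts[0]), parts[2], int(parts[3]), parts[5], float(parts[6])
                )
            )
    return restraints
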