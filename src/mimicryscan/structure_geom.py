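"""Structural mimicry layer.

Peptides bound in the HLA class I groove expose only their central residues
to the T-cell receptor; two peptides are structural mimics when the planar
(three-atom) and dihedral (four-atom torsion) angles over selected atoms of
those TCR-facing residues agree within +/-10%.  This module parses
peptide-HLA(-TCR) coordinates from PDB text, assigns per-residue contacts to
the HLA and TCR chains by a heavy-atom distance cutoff, computes angles over
configurable atom selections and applies the angle-identity criterion.

Angle conventions: planar angles in [0, 180] degrees; dihedrals signed in
(-180, 180] with the IUPAC convention (cis = 0, trans = 180).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CHAIN_ROLES = ("peptide", "hla", "b2m", "tcr_alpha", "tcr_beta")
CONTACT_CATEGORIES = {"hla": "HLA", "tcr_alpha": "TCR_alpha", "tcr_beta": "TCR_beta"}

#: Peptide chain length accepted by the parser (HLA class I ligands).
PEPTIDE_LENGTH_RANGE = (8, 11)

#: Relative angle-identity tolerance and the small-angle absolute floor.
ANGLE_TOLERANCE = 0.10
SMALL_ANGLE_FLOOR_DEG = 5.0
SMALL_ANGLE_CUTOFF_DEG = 50.0

#: Static TCR-facing fallback: central positions, anchors 2 and 9 excluded.
STATIC_TCR_FACING = frozenset({4, 5, 6, 7, 8})

DEFAULT_CONTACT_CUTOFF_A = 4.0


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    name: str  # 3-letter code
    seq_number: int
    atoms: dict[str, Atom] = field(default_factory=dict)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms.values() if a.element != "H"]


@dataclass
class PeptideStructure:
    """Parsed coordinates with chain roles assigned.

    ``chains`` maps chain id -> ordered residues; ``roles`` maps chain id ->
    one of ``peptide | hla | b2m | tcr_alpha | tcr_beta``.
    """

    structure_id: str
    chains: dict[str, list[Residue]]
    roles: dict[str, str] = field(default_factory=dict)

    def chain_by_role(self, role: str) -> tuple[str, list[Residue]] | None:
        for cid, r in self.roles.items():
            if r == role:
                return cid, self.chains[cid]
        return None

    @property
    def peptide_chain(self) -> list[Residue]:
        found = self.chain_by_role("peptide")
        if found is None:
            raise ValueError(f"{self.structure_id}: no chain with role 'peptide'")
        return found[1]

    def peptide_sequence_length(self) -> int:
        return len(self.peptide_chain)


# ---------------------------------------------------------------------------
# PDB parsing (fixed-column ATOM/HETATM subset)
# ---------------------------------------------------------------------------

def parse_pdb(
    source: str | Path | Iterable[str],
    chain_roles: Mapping[str, str],
    structure_id: str = "",
) -> PeptideStructure:
    """Parse ATOM/HETATM records from PDB-format text.

    ``chain_roles`` maps chain ids to roles; only listed chains are kept.
    Alternate locations: altloc 'A' or blank retained, others dropped.  The
    peptide chain must have 8-11 residues.  Malformed ATOM lines and missing
    declared chains raise with the offending line / chain named.
    """
    for cid, role in chain_roles.items():
        if role not in CHAIN_ROLES:
            raise ValueError(f"unknown chain role {role!r} for chain {cid!r}")
    if "peptide" not in chain_roles.values():
        raise ValueError("chain_roles must assign a 'peptide' chain")

    if isinstance(source, (str, Path)):
        path = Path(source)
        if not structure_id:
            structure_id = path.stem
        lines: Iterable[str] = path.read_text().splitlines()
    else:
        lines = source

    chains: dict[str, dict[int, Residue]] = {cid: {} for cid in chain_roles}
    n_atom_records = 0
    for line_no, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_atom_records += 1
        try:
            atom_name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip()
            seq_number = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed ATOM record at line {line_no}: {line!r}") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = atom_name[:1]
        if chain_id not in chains:
            continue
        if altloc not in ("", "A"):
            continue
        residues = chains[chain_id]
        if seq_number not in residues:
            residues[seq_number] = Residue(name=res_name, seq_number=seq_number)
        res = residues[seq_number]
        if atom_name not in res.atoms:  # first occurrence wins (altloc rule)
            res.atoms[atom_name] = Atom(name=atom_name, element=element, xyz=(x, y, z))

    if n_atom_records == 0:
        raise ValueError(f"{structure_id or 'input'}: no ATOM/HETATM records")
    for cid in chain_roles:
        if not chains[cid]:
            raise ValueError(f"declared chain {cid!r} not found in {structure_id or 'input'}")

    ordered = {cid: [residues[k] for k in sorted(residues)] for cid, residues in chains.items()}
    structure = PeptideStructure(
        structure_id=structure_id or "structure",
        chains=ordered,
        roles=dict(chain_roles),
    )
    n_pep = structure.peptide_sequence_length()
    lo, hi = PEPTIDE_LENGTH_RANGE
    if not lo <= n_pep <= hi:
        raise ValueError(
            f"{structure.structure_id}: peptide chain has {n_pep} residues, expected {lo}-{hi}"
        )
    return structure


def write_pdb(structure: PeptideStructure, path: str | Path) -> None:
    """Write ATOM records (fixed-column) for all chains of a structure."""
    serial = 0
    with open(path, "w") as fh:
        for cid, residues in structure.chains.items():
            for res in residues:
                for atom in res.atoms.values():
                    serial += 1
                    x, y, z = atom.xyz
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} {cid}"
                        f"{res.seq_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                    )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Angle primitives
# ---------------------------------------------------------------------------

def planar_angle(p1, p2, p3) -> float:
    """Angle in degrees at vertex p2 between vectors p2->p1 and p2->p3."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("coincident points in planar angle")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion about the p2-p3 axis, degrees in (-180, 180], IUPAC sign."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate (collinear) geometry in dihedral angle")
    b2u = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2u)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 and math.isclose(abs(ang), 180.0) else ang


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest absolute difference between two angles on the circle, degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# Descriptors and the +/-10% comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleDescriptor:
    """An angle to measure: 3 (planar) or 4 (dihedral) (position, atom) refs.

    Positions are 1-based within the peptide chain.
    """

    kind: str  # "planar" | "dihedral"
    atom_refs: tuple[tuple[int, str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        need = {"planar": 3, "dihedral": 4}.get(self.kind)
        if need is None:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if len(self.atom_refs) != need:
            raise ValueError(f"{self.kind} descriptor needs {need} atom refs")


@dataclass(frozen=True)
class AngleComparison:
    descriptor: AngleDescriptor
    value_ref: float
    value_alt: float
    relative_difference: float
    identical: bool


def _resolve(structure: PeptideStructure, ref: tuple[int, str]) -> tuple[float, float, float]:
    pos, atom_name = ref
    chain = structure.peptide_chain
    if not 1 <= pos <= len(chain):
        raise ValueError(f"peptide position {pos} out of range in {structure.structure_id}")
    res = chain[pos - 1]
    if atom_name not in res.atoms:
        raise ValueError(
            f"atom {atom_name!r} missing at peptide position {pos} "
            f"({res.name}{res.seq_number}) in {structure.structure_id}"
        )
    return res.atoms[atom_name].xyz


def measure_angle(structure: PeptideStructure, descriptor: AngleDescriptor) -> float:
    points = [_resolve(structure, ref) for ref in descriptor.atom_refs]
    if descriptor.kind == "planar":
        return planar_angle(*points)
    return dihedral_angle(*points)


def angles_identical(value_ref: float, value_alt: float, tolerance: float = ANGLE_TOLERANCE) -> bool:
    """The +/-10% criterion with a 5 deg absolute floor below 50 deg.

    The circular difference must not exceed tolerance x |reference angle|;
    near-zero reference angles would make the relative criterion unpassable,
    so an absolute floor of 5 deg applies when |ref| < 50 deg.
    """
    d = circular_difference_deg(value_ref, value_alt)
    band = tolerance * abs(value_ref)
    if abs(value_ref) < SMALL_ANGLE_CUTOFF_DEG:
        band = max(band, SMALL_ANGLE_FLOOR_DEG)
    return d <= band


def compare_angles(
    ref_structure: PeptideStructure,
    alt_structure: PeptideStructure,
    descriptors: Sequence[AngleDescriptor],
    tolerance: float = ANGLE_TOLERANCE,
    magnitude_only: bool = False,
) -> tuple[list[AngleComparison], float]:
    """Measure each descriptor in both structures and apply the identity criterion.

    Returns the per-descriptor comparisons and ``percent_identical`` (0-100).
    ``magnitude_only`` compares |angle| values instead of signed ones.
    """
    if not descriptors:
        raise ValueError("no descriptors to compare")
    comparisons = []
    for desc in descriptors:
        v_ref = measure_angle(ref_structure, desc)
        v_alt = measure_angle(alt_structure, desc)
        if magnitude_only:
            v_ref_c, v_alt_c = abs(v_ref), abs(v_alt)
        else:
            v_ref_c, v_alt_c = v_ref, v_alt
        ident = angles_identical(v_ref_c, v_alt_c, tolerance)
        d = circular_difference_deg(v_ref_c, v_alt_c)
        rel = d / abs(v_ref_c) if abs(v_ref_c) > 1e-12 else math.inf
        comparisons.append(
            AngleComparison(
                descriptor=desc,
                value_ref=v_ref,
                value_alt=v_alt,
                relative_difference=rel,
                identical=ident,
            )
        )
    pct = 100.0 * sum(c.identical for c in comparisons) / len(comparisons)
    return comparisons, pct


#: Heavy side-chain atom furthest along each side chain (terminal atom used
#: by the default side-chain dihedral descriptor).
_TERMINAL_SIDECHAIN_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "ND2", "ASP": "OD1", "CYS": "SG",
    "GLN": "NE2", "GLU": "OE1", "HIS": "NE2", "ILE": "CD1", "LEU": "CD1",
    "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "OG1", "TRP": "CH2", "TYR": "OH", "VAL": "CG1",
}


def default_descriptors(
    structure: PeptideStructure, positions: Iterable[int] | None = None
) -> list[AngleDescriptor]:
    """Default angle set over the TCR-facing positions.

    Per position i: the backbone-path planar angle (CA_{i-1}, CA_i, CA_{i+1})
    and, where the residue has a side chain beyond C-beta, the side-chain
    orientation dihedral (N_i, CA_i, CB_i, terminal side-chain atom).
    Descriptors whose atoms are absent in the structure are skipped.
    """
    chain = structure.peptide_chain
    n = len(chain)
    if positions is None:
        positions = sorted(p for p in STATIC_TCR_FACING if 1 < p < n)
    out: list[AngleDescriptor] = []
    for pos in positions:
        if 1 < pos < n:
            refs = ((pos - 1, "CA"), (pos, "CA"), (pos + 1, "CA"))
            if all(r[1] in chain[r[0] - 1].atoms for r in refs):
                out.append(AngleDescriptor("planar", refs, label=f"CA-path@{pos}"))
        res = chain[pos - 1]
        terminal = _TERMINAL_SIDECHAIN_ATOM.get(res.name)
        if terminal and terminal != "CB":
            refs4 = ((pos, "N"), (pos, "CA"), (pos, "CB"), (pos, terminal))
            if all(r[1] in res.atoms for r in refs4):
                out.append(AngleDescriptor("dihedral", refs4, label=f"sidechain@{pos}"))
    if not out:
        raise ValueError(f"{structure.structure_id}: no resolvable default descriptors")
    return out


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactMap:
    """Per peptide position (1-based): contact categories within the cutoff."""

    contacts: dict[int, frozenset[str]]
    cutoff_A: float

    def positions_contacting(self, category: str) -> set[int]:
        return {pos for pos, cats in self.contacts.items() if category in cats}


def contact_map(structure: PeptideStructure, cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A) -> ContactMap:
    """Assign HLA / TCR-alpha / TCR-beta contact categories to peptide residues.

    A residue carries a category iff any of its heavy atoms lies within the
    cutoff of any heavy atom of a chain with that role; the beta-2
    microglobulin chain never generates a category.
    """
    peptide = structure.peptide_chain  # raises if absent
    partner_coords: dict[str, np.ndarray] = {}
    for cid, role in structure.roles.items():
        if role in CONTACT_CATEGORIES:
            coords = [a.xyz for res in structure.chains[cid] for a in res.heavy_atoms()]
            if coords:
                cat = CONTACT_CATEGORIES[role]
                prev = partner_coords.get(cat)
                arr = np.asarray(coords)
                partner_coords[cat] = arr if prev is None else np.vstack([prev, arr])

    contacts: dict[int, frozenset[str]] = {}
    for pos, res in enumerate(peptide, start=1):
        res_coords = np.asarray([a.xyz for a in res.heavy_atoms()])
        cats = set()
        if len(res_coords) and cutoff_A > 0:
            for cat, arr in partner_coords.items():
                d2 = ((res_coords[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
                if (d2 <= cutoff_A ** 2).any():
                    cats.add(cat)
        contacts[pos] = frozenset(cats)
    return ContactMap(contacts=contacts, cutoff_A=cutoff_A)


def tcr_facing_positions(source: ContactMap | str | None = None) -> set[int]:
    """Peptide positions exposed to the TCR.

    From a :class:`ContactMap`: positions contacting either TCR chain; if the
    map carries no TCR contacts at all (structure without TCR chains), or when
    given an allele label / nothing, the static central-position fallback
    {4,5,6,7,8} is returned (anchors 2 and 9 are buried in the HLA groove).
    """
    if isinstance(source, ContactMap):
        pos = source.positions_contacting("TCR_alpha") | source.positions_contacting("TCR_beta")
        if pos:
            return pos
        logger.info("no TCR contacts in map; using static fallback %s", sorted(STATIC_TCR_FACING))
    return set(STATIC_TCR_FACING)
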