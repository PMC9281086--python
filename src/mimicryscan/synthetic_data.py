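"""Seeded generators for every input the pipeline consumes.

Real runs of this analysis depend on external databases and prediction
servers; the generators here produce the same *kinds* of input — bacterial
proteomes with homologs planted at controlled identity and substitution-class
composition, binding-prediction tables, and idealized peptide coordinates
with specified backbone torsions — with full determinism from a seed, so
every downstream stage is testable against a known ground truth (the plant
ledger).

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mimicry_core import (
    CONSERVATIVE,
    EPITOPE_LENGTH,
    NON_CONSERVATIVE,
    STANDARD_AA,
    EpitopeRecord,
    ProteinRecord,
    SubstitutionScheme,
    classify_substitution,
)
from .structure_geom import Atom, PeptideStructure, Residue

#: Uniform background: each of the 20 residues at 1/20, the assumption behind
#: the random-stretch probability model.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)

#: Approximate Swiss-Prot residue composition (fractions), alternative
#: background for more protein-like synthetic proteomes.
SWISSPROT_BACKGROUND = np.array([
    0.0826, 0.0139, 0.0546, 0.0672, 0.0387, 0.0708, 0.0228, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0665, 0.0536, 0.0686,
    0.0110, 0.0292,
])
SWISSPROT_BACKGROUND = SWISSPROT_BACKGROUND / SWISSPROT_BACKGROUND.sum()


# ---------------------------------------------------------------------------
# Proteome generation and homolog planting
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 300),
    background_freqs: np.ndarray | None = None,
    seed: int = 0,
    phylum: str = "other",
    id_prefix: str = "SYN",
) -> list[ProteinRecord]:
    """Random protein records with residues drawn iid from a background."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < EPITOPE_LENGTH:
        raise ValueError(f"minimum length must be >= {EPITOPE_LENGTH}")
    freqs = UNIFORM_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    if freqs.shape != (20,) or (freqs < 0).any() or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background_freqs must be a nonnegative 20-vector summing to 1")
    freqs = freqs / freqs.sum()

    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length, p=freqs))
        records.append(
            ProteinRecord(
                protein_id=f"{id_prefix}_{i:05d}",
                description=f"synthetic protein ({phylum})",
                sequence=seq,
                phylum=phylum,
            )
        )
    return records


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted homolog."""

    antigen_name: str
    epitope_sequence: str
    protein_id: str
    offset: int  # 0-based
    planted_sequence: str
    n_substitutions: int
    substitution_positions: tuple[int, ...]  # 1-based
    substitution_classes: tuple[str, ...]


@dataclass
class PlantLedger:
    """Everything needed to predict the scanner's recovery of planted homologs."""

    seed: int
    background: str = "uniform"
    records: list[PlantRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "background": self.background,
                    "records": [asdict(r) for r in self.records],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantLedger":
        data = json.loads(Path(path).read_text())
        ledger = cls(seed=data["seed"], background=data["background"])
        for r in data["records"]:
            r["substitution_positions"] = tuple(r["substitution_positions"])
            r["substitution_classes"] = tuple(r["substitution_classes"])
            ledger.records.append(PlantRecord(**r))
        return ledger


def _substitute_residue(
    residue: str, policy: str, scheme: SubstitutionScheme, rng: np.random.Generator
) -> tuple[str, str] | None:
    """A replacement residue satisfying the class policy, or None if impossible."""
    wanted = {
        "conservative_only": {CONSERVATIVE},
        "non_conservative_only": {NON_CONSERVATIVE},
        "mixed": {CONSERVATIVE, NON_CONSERVATIVE},
    }.get(policy)
    if wanted is None:
        raise ValueError(f"unknown class_policy {policy!r}")
    candidates = [
        (aa, classify_substitution(residue, aa, scheme))
        for aa in STANDARD_AA
        if aa != residue and classify_substitution(residue, aa, scheme) in wanted
    ]
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def plant_homolog(
    proteome: list[ProteinRecord],
    epitope: EpitopeRecord,
    n_substitutions: int,
    class_policy: str = "mixed",
    positions: list[int] | None = None,
    seed: int = 0,
    ledger: PlantLedger | None = None,
    scheme: SubstitutionScheme | None = None,
    max_retries: int = 50,
) -> tuple[list[ProteinRecord], PlantRecord]:
    """Overwrite a 9-residue window of a random protein with a mutated epitope.

    The planted 9-mer differs from the epitope at exactly ``n_substitutions``
    positions (1-based ``positions`` if given, otherwise random), each
    replacement drawn according to ``class_policy`` under the substitution
    scheme.  Planting overwrites in place (protein lengths unchanged) and
    never overlaps a previously planted window of the same ledger.

    Returns the modified proteome (new list, input untouched) and the ledger
    record; the record is also appended to ``ledger`` when one is passed.
    """
    if not 0 <= n_substitutions <= EPITOPE_LENGTH:
        raise ValueError("n_substitutions must be in [0, 9]")
    scheme = scheme or SubstitutionScheme()
    rng = np.random.default_rng(seed)

    occupied: dict[str, list[tuple[int, int]]] = {}
    if ledger is not None:
        for r in ledger.records:
            occupied.setdefault(r.protein_id, []).append((r.offset, r.offset + EPITOPE_LENGTH))

    eligible = [i for i, p in enumerate(proteome) if len(p.sequence) >= EPITOPE_LENGTH]
    if not eligible:
        raise ValueError("no protein long enough to host a planted homolog")

    for _ in range(max_retries):
        idx = eligible[int(rng.integers(len(eligible)))]
        protein = proteome[idx]
        offset = int(rng.integers(len(protein.sequence) - EPITOPE_LENGTH + 1))
        window = (offset, offset + EPITOPE_LENGTH)
        if any(window[0] < e and s < window[1] for s, e in occupied.get(protein.protein_id, [])):
            continue

        if positions is not None:
            if len(positions) != n_substitutions:
                raise ValueError("positions length must equal n_substitutions")
            sub_pos = sorted(positions)
            if any(not 1 <= p <= EPITOPE_LENGTH for p in sub_pos):
                raise ValueError("substitution positions must be 1-based in [1, 9]")
        else:
            sub_pos = sorted(
                int(p) + 1
                for p in rng.choice(EPITOPE_LENGTH, size=n_substitutions, replace=False)
            )

        planted = list(epitope.sequence)
        classes = []
        feasible = True
        for p in sub_pos:
            choice = _substitute_residue(planted[p - 1], class_policy, scheme, rng)
            if choice is None:
                feasible = False
                break
            planted[p - 1], label = choice
            classes.append(label)
        if not feasible:
            if positions is not None:
                raise ValueError(
                    f"class_policy {class_policy!r} unsatisfiable at position(s) {sub_pos}"
                )
            continue  # reselect positions on the next retry

        planted_seq = "".join(planted)
        new_seq = (
            protein.sequence[:offset] + planted_seq + protein.sequence[offset + EPITOPE_LENGTH:]
        )
        new_proteome = list(proteome)
        new_proteome[idx] = ProteinRecord(
            protein_id=protein.protein_id,
            description=protein.description,
            sequence=new_seq,
            phylum=protein.phylum,
        )
        record = PlantRecord(
            antigen_name=epitope.antigen_name,
            epitope_sequence=epitope.sequence,
            protein_id=protein.protein_id,
            offset=offset,
            planted_sequence=planted_seq,
            n_substitutions=n_substitutions,
            substitution_positions=tuple(sub_pos),
            substitution_classes=tuple(classes),
        )
        if ledger is not None:
            ledger.records.append(record)
        return new_proteome, record

    raise ValueError(f"could not place homolog after {max_retries} retries")


# ---------------------------------------------------------------------------
# Idealized peptide coordinates (NeRF construction)
# ---------------------------------------------------------------------------

# Standard backbone geometry (Engh-Huber-style averages), Angstroms / degrees.
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.4
_T_OMEGA = 180.0
_T_N_CA_CB = -122.0  # C'-N-CA-CB pseudo-torsion giving L-chirality

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: position D from A-B-C with given
    C-D bond length, B-C-D angle and A-B-C-D torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta, phi = math.radians(angle_deg), math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def generate_ideal_peptide(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    seed: int = 0,
    structure_id: str = "IDEAL",
    chain_id: str = "P",
) -> PeptideStructure:
    """Peptide-only structure with backbone N/CA/C/O and C-beta stubs.

    ``phi_psi`` supplies one (phi, psi) pair per residue in degrees.  Standard
    bond lengths and angles are used; the backbone torsions measured from the
    emitted coordinates reproduce the requested values to well under 1e-3 deg
    (phi of the first residue and psi of the last are not realized — they
    need atoms outside the chain).  ``seed`` is accepted for interface
    uniformity; the construction is fully deterministic.
    """
    sequence = sequence.upper()
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi must supply one (phi, psi) pair per residue")
    for phi, psi in phi_psi:
        if not (math.isfinite(phi) and math.isfinite(psi)):
            raise ValueError("torsions must be finite")
    if any(aa not in _AA3 for aa in sequence):
        raise ValueError("sequence must use standard residues")

    n_res = len(sequence)
    # Seed frame: residue 1 backbone in the xy-plane.
    coords: list[dict[str, np.ndarray]] = [{} for _ in range(n_res)]
    coords[0]["N"] = np.zeros(3)
    coords[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    coords[0]["C"] = coords[0]["CA"] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    for i in range(n_res):
        phi_next = phi_psi[i + 1][0] if i + 1 < n_res else None
        psi_i = phi_psi[i][1]
        if i + 1 < n_res:
            coords[i + 1]["N"] = _place_atom(
                coords[i]["N"], coords[i]["CA"], coords[i]["C"],
                _B_C_N, _A_CA_C_N, psi_i,
            )
            coords[i + 1]["CA"] = _place_atom(
                coords[i]["CA"], coords[i]["C"], coords[i + 1]["N"],
                _B_N_CA, _A_C_N_CA, _T_OMEGA,
            )
            coords[i + 1]["C"] = _place_atom(
                coords[i]["C"], coords[i + 1]["N"], coords[i + 1]["CA"],
                _B_CA_C, _A_N_CA_C, phi_next,
            )
        # carbonyl O: anti to the next N (psi + 180)
        coords[i]["O"] = _place_atom(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"],
            _B_C_O, _A_CA_C_O, psi_i + 180.0,
        )
        if sequence[i] != "G":
            coords[i]["CB"] = _place_atom(
                coords[i]["C"], coords[i]["N"], coords[i]["CA"],
                _B_CA_CB, _A_N_CA_CB, _T_N_CA_CB,
            )

    residues = []
    for i, aa in enumerate(sequence):
        res = Residue(name=_AA3[aa], seq_number=i + 1)
        for name, xyz in coords[i].items():
            element = name[0]
            res.atoms[name] = Atom(name=name, element=element, xyz=tuple(float(v) for v in xyz))
        residues.append(res)
    return PeptideStructure(
        structure_id=structure_id,
        chains={chain_id: residues},
        roles={chain_id: "peptide"},
    )


def measure_backbone_torsions(structure: PeptideStructure) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue measured from coordinates; None where undefined."""
    from .structure_geom import dihedral_angle

    chain = structure.peptide_chain
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(chain):
        phi = psi = None
        if i > 0:
            phi = dihedral_angle(
                chain[i - 1].atoms["C"].xyz, res.atoms["N"].xyz,
                res.atoms["CA"].xyz, res.atoms["C"].xyz,
            )
        if i + 1 < len(chain):
            psi = dihedral_angle(
                res.atoms["N"].xyz, res.atoms["CA"].xyz,
                res.atoms["C"].xyz, chain[i + 1].atoms["N"].xyz,
            )
        out.append((phi, psi))
    return out
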