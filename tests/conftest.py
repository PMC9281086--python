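import numpy as np
import pytest

from mimicryscan import (
    EpitopeRecord,
    MimicryHit,
    ProteinRecord,
    classify_pair,
)
from mimicryscan.structure_geom import Atom, PeptideStructure, Residue


@pytest.fixture
def mage_a3():
    return EpitopeRecord("MAGE-A3", "KVAELVHFL", "HLA-A*02:01")


@pytest.fixture
def mage_a10():
    return EpitopeRecord("MAGE-A10", "GLYDGMEHL", "HLA-A*02:01")


def make_hit(epitope: EpitopeRecord, hit_seq: str, protein_id="P1", offset=0, phylum="Firmicutes"):
    labels, n_ident = classify_pair(epitope.sequence, hit_seq)
    return MimicryHit(
        epitope=epitope,
        hit_sequence=hit_seq,
        protein_id=protein_id,
        offset=offset,
        position_labels=labels,
        identity_count=n_ident,
        phylum=phylum,
    )


@pytest.fixture
def hit_factory():
    return make_hit


def make_residue(name: str, seq_number: int, atoms: dict[str, tuple[float, float, float]]):
    res = Residue(name=name, seq_number=seq_number)
    for atom_name, xyz in atoms.items():
        res.atoms[atom_name] = Atom(name=atom_name, element=atom_name[0], xyz=xyz)
    return res


@pytest.fixture
def contact_fixture_structure():
    """Synthetic peptide-HLA-TCR complex with planted contacts.

    Nine peptide CA atoms 3.8 A apart along x.  One HLA atom 3.5 A from
    peptide residue 3, one TCR-alpha atom 3.0 A from residue 5, one TCR-beta
    atom 3.9 A from residue 8; everything else is far (> 6 A).
    """
    peptide = [
        make_residue("ALA", i + 1, {"CA": (3.8 * i, 0.0, 0.0)}) for i in range(9)
    ]
    hla = [make_residue("GLY", 1, {"CA": (3.8 * 2, 3.5, 0.0)}),
           make_residue("GLY", 2, {"CA": (0.0, 50.0, 0.0)})]
    tcr_a = [make_residue("GLY", 1, {"CA": (3.8 * 4, 0.0, 3.0)})]
    tcr_b = [make_residue("GLY", 1, {"CA": (3.8 * 7, -3.9, 0.0)})]
    return PeptideStructure(
        structure_id="FIXTURE",
        chains={"C": peptide, "A": hla, "D": tcr_a, "E": tcr_b},
        roles={"C": "peptide", "A": "hla", "D": "tcr_alpha", "E": "tcr_beta"},
    )
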