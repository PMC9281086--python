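"""Core domain types and pairwise nonamer classification.

Tumor-associated antigen (TAA) epitopes presented on HLA class I are nine
residues long.  A bacterial peptide "mimics" a TAA epitope when, aligned
without gaps, its residues are mostly identical or conservative substitutions
(same physicochemical class).  This module holds the shared record types, the
substitution scheme, and the position-wise classifier that everything
downstream builds on.

Position convention: user-facing positions are 1-based (position 2 is the
HLA-A*02:01 anchor); internal indices are 0-based.  Every interface that
reports positions says which convention it uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes tolerated in protein sequences but never
#: inside a scan window.
AMBIGUOUS_AA: frozenset[str] = frozenset("XBZUO")

#: Default physicochemical partition of the standard residues.  Every colour
#: -coded substitution in the worked alignment examples (I/V, L/M, L/V) is
#: conservative under this grouping.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AVLIM"),
    "aromatic": frozenset("FWY"),
    "polar_uncharged": frozenset("STNQC"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "special": frozenset("GP"),
}

IDENTICAL = "identical"
CONSERVATIVE = "conservative"
NON_CONSERVATIVE = "non_conservative"

#: Single-letter codes used in the 9-character label string of hit tables.
LABEL_CODES = {IDENTICAL: "I", CONSERVATIVE: "C", NON_CONSERVATIVE: "N"}

EPITOPE_LENGTH = 9


class ResidueError(ValueError):
    """A character is not one of the 20 standard one-letter residue codes."""


def _check_residue(ch: str) -> str:
    ch = ch.upper()
    if ch not in STANDARD_AA:
        raise ResidueError(f"non-standard residue {ch!r}")
    return ch


def _check_nonamer(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if len(seq) != EPITOPE_LENGTH:
        raise ValueError(f"{what} must have length {EPITOPE_LENGTH}, got {len(seq)}: {seq!r}")
    for ch in seq:
        _check_residue(ch)
    return seq


@dataclass(frozen=True)
class SubstitutionScheme:
    """How a residue pair is labelled identical / conservative / non-conservative.

    Two modes:

    ``class_partition``
        residues of the same physicochemical class are conservative;
        ``classes`` must partition the 20 standard residues.
    ``matrix_nonnegative``
        a substitution-matrix score >= 0 is conservative (BLOSUM62 by
        default); ``classes`` is ignored.
    """

    classes: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    mode: str = "class_partition"

    def __post_init__(self) -> None:
        if self.mode not in ("class_partition", "matrix_nonnegative"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.mode == "class_partition":
            seen: dict[str, str] = {}
            for name, members in self.classes.items():
                for aa in members:
                    if aa in seen:
                        raise ValueError(
                            f"residue {aa} in both {seen[aa]!r} and {name!r}"
                        )
                    seen[aa] = name
            missing = set(STANDARD_AA) - set(seen)
            if missing:
                raise ValueError(f"residues not covered by partition: {sorted(missing)}")

    def class_of(self, residue: str) -> str:
        residue = _check_residue(residue)
        for name, members in self.classes.items():
            if residue in members:
                return name
        raise ResidueError(f"residue {residue!r} not in any class")  # pragma: no cover


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def classify_substitution(a: str, b: str, scheme: SubstitutionScheme | None = None) -> str:
    """Label a residue pair.

    ``identical`` iff ``a == b``; otherwise ``conservative`` when the two
    residues share a physicochemical class (``class_partition`` mode) or score
    >= 0 under BLOSUM62 (``matrix_nonnegative`` mode); else
    ``non_conservative``.  Symmetric in its arguments.
    """
    scheme = scheme or SubstitutionScheme()
    a, b = _check_residue(a), _check_residue(b)
    if a == b:
        return IDENTICAL
    if scheme.mode == "class_partition":
        return CONSERVATIVE if scheme.class_of(a) == scheme.class_of(b) else NON_CONSERVATIVE
    return CONSERVATIVE if _blosum62()[a, b] >= 0 else NON_CONSERVATIVE


def classify_pair(
    epitope_seq: str, hit_seq: str, scheme: SubstitutionScheme | None = None
) -> tuple[tuple[str, ...], int]:
    """Position-wise labels and identity count for an ungapped nonamer pair.

    Returns ``(labels, identity_count)`` where ``labels`` has one entry per
    position (0-based internally) and ``identity_count`` is the number of
    ``identical`` labels.
    """
    epitope_seq = _check_nonamer(epitope_seq, "epitope")
    hit_seq = _check_nonamer(hit_seq, "hit")
    labels = tuple(
        classify_substitution(a, b, scheme) for a, b in zip(epitope_seq, hit_seq)
    )
    return labels, sum(lab == IDENTICAL for lab in labels)


def labels_to_string(labels: Sequence[str]) -> str:
    """Compact 9-character I/C/N encoding used in hit tables."""
    return "".join(LABEL_CODES[lab] for lab in labels)


@dataclass(frozen=True)
class EpitopeRecord:
    """A TAA nonamer with its antigen name and HLA restriction."""

    antigen_name: str
    sequence: str
    hla_allele: str
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.antigen_name:
            raise ValueError("antigen_name must be non-empty")
        object.__setattr__(self, "sequence", _check_nonamer(self.sequence, "epitope"))


@dataclass(frozen=True)
class ProteinRecord:
    """A bacterial protein sequence with a phylum label.

    ``sequence`` may contain the ambiguity codes X/B/Z/U/O; the scanner skips
    windows that touch them.
    """

    protein_id: str
    sequence: str
    description: str = ""
    phylum: str = "other"

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set(STANDARD_AA) - AMBIGUOUS_AA
        if bad:
            raise ValueError(f"protein {self.protein_id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MimicryHit:
    """One ungapped alignment of a bacterial 9-mer window to a TAA epitope.

    ``offset`` is the 0-based start of the window within the protein; output
    tables report ``offset + 1``.
    """

    epitope: EpitopeRecord
    hit_sequence: str
    protein_id: str
    offset: int
    position_labels: tuple[str, ...]
    identity_count: int
    phylum: str = "other"

    def __post_init__(self) -> None:
        if len(self.position_labels) != EPITOPE_LENGTH:
            raise ValueError("position_labels must have length 9")
        n_ident = sum(lab == IDENTICAL for lab in self.position_labels)
        if n_ident != self.identity_count:
            raise ValueError(
                f"identity_count {self.identity_count} != {n_ident} identical labels"
            )
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        object.__setattr__(self, "hit_sequence", _check_nonamer(self.hit_sequence, "hit"))

    @property
    def label_string(self) -> str:
        return labels_to_string(self.position_labels)


# ---------------------------------------------------------------------------
# I/O: epitope TSV and protein FASTA
# ---------------------------------------------------------------------------

def read_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read a TSV with columns antigen_name, sequence, hla_allele[, source_note]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"antigen_name", "sequence", "hla_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epitope table {path}: missing columns {sorted(missing)}")
    return [
        EpitopeRecord(
            antigen_name=row.antigen_name,
            sequence=row.sequence,
            hla_allele=row.hla_allele,
            source_note=getattr(row, "source_note", ""),
        )
        for row in df.itertuples(index=False)
    ]


def read_fasta(path: str | Path, phylum: str = "other") -> list[ProteinRecord]:
    """Read a multi-FASTA of proteins, tagging every record with ``phylum``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                sequence=str(rec.seq),
                phylum=phylum,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.protein_id}{desc}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


#: Worked-example epitopes with printed sequences: the two MAGE antigens used
#: in the backbone comparison and the reference-complex peptides (HTLV-1 Tax
#: nonamer from the 1AO7 crystal, influenza NP nonamer from 7JYV).
EXAMPLE_EPITOPES: tuple[EpitopeRecord, ...] = (
    EpitopeRecord("MAGE-A3", "KVAELVHFL", "HLA-A*02:01", source_note="CAPED"),
    EpitopeRecord("MAGE-A10", "GLYDGMEHL", "HLA-A*02:01", source_note="CAPED"),
    EpitopeRecord("HTLV-1-Tax", "LLFGYPVYV", "HLA-A*02:01", source_note="1AO7 reference"),
    EpitopeRecord("Flu-NP", "YFSPIRVTF", "HLA-A*24:02", source_note="7JYV reference"),
)
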