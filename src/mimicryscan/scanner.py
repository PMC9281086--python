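"""Exhaustive ungapped 9-mer proteome scanning.

Every 9-residue window of every protein is compared, position by position,
against every query epitope; windows with at least ``min_identity`` identical
residues become :class:`~mimicryscan.mimicry_core.MimicryHit` records.  This
replaces a gapped, statistics-driven homology search with a complete and
exactly reproducible enumeration — defensible because every alignment the
analysis consumes is a gapless nonamer pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .mimicry_core import (
    AMBIGUOUS_AA,
    EPITOPE_LENGTH,
    EpitopeRecord,
    MimicryHit,
    ProteinRecord,
    SubstitutionScheme,
    classify_pair,
)

logger = logging.getLogger(__name__)

HIGH_AFFINITY_NM = 10.0  # "high affinity" threshold, nM


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``min_identity`` defaults to 5: reported homologs go down to 51% identity,
    i.e. at least 5 of 9 residues.  ``skip_ambiguous`` drops windows containing
    X/B/Z/U/O rather than penalising them.
    """

    min_identity: int = 5
    skip_ambiguous: bool = True
    max_hits_per_epitope: int | None = None
    scheme: SubstitutionScheme = field(default_factory=SubstitutionScheme)

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= EPITOPE_LENGTH:
            raise ValueError(f"min_identity must be in [0, 9], got {self.min_identity}")


def scan_proteome(
    epitopes: list[EpitopeRecord],
    proteins: list[ProteinRecord],
    config: ScanConfig | None = None,
) -> list[MimicryHit]:
    """All windows with identity >= ``min_identity`` for every epitope.

    Hits are ordered deterministically by (antigen_name, descending
    identity_count, protein_id, offset).  Proteins shorter than 9 residues
    yield no windows (logged, not an error).
    """
    config = config or ScanConfig()
    if not epitopes:
        raise ValueError("epitope list is empty")

    hits: list[MimicryHit] = []
    for protein in proteins:
        seq = protein.sequence
        if len(seq) < EPITOPE_LENGTH:
            logger.debug("protein %s shorter than 9 residues; skipped", protein.protein_id)
            continue
        for offset in range(len(seq) - EPITOPE_LENGTH + 1):
            window = seq[offset : offset + EPITOPE_LENGTH]
            if set(window) & AMBIGUOUS_AA:
                if config.skip_ambiguous:
                    continue
                raise ValueError(
                    f"ambiguous residue in window {window!r} of {protein.protein_id} "
                    f"at offset {offset} with skip_ambiguous=False"
                )
            for epitope in epitopes:
                labels, n_ident = classify_pair(epitope.sequence, window, config.scheme)
                if n_ident >= config.min_identity:
                    hits.append(
                        MimicryHit(
                            epitope=epitope,
                            hit_sequence=window,
                            protein_id=protein.protein_id,
                            offset=offset,
                            position_labels=labels,
                            identity_count=n_ident,
                            phylum=protein.phylum,
                        )
                    )

    hits.sort(
        key=lambda h: (h.epitope.antigen_name, -h.identity_count, h.protein_id, h.offset)
    )
    if config.max_hits_per_epitope is not None:
        capped: list[MimicryHit] = []
        seen: dict[str, int] = {}
        for h in hits:
            k = h.epitope.antigen_name
            if seen.get(k, 0) < config.max_hits_per_epitope:
                capped.append(h)
                seen[k] = seen.get(k, 0) + 1
        hits = capped
    return hits


def hits_to_frame(hits: list[MimicryHit]) -> pd.DataFrame:
    """Tabular view of a hit list (offset reported 1-based)."""
    return pd.DataFrame(
        {
            "antigen_name": [h.epitope.antigen_name for h in hits],
            "epitope": [h.epitope.sequence for h in hits],
            "hla_allele": [h.epitope.hla_allele for h in hits],
            "hit_sequence": [h.hit_sequence for h in hits],
            "protein_id": [h.protein_id for h in hits],
            "offset_1based": [h.offset + 1 for h in hits],
            "phylum": [h.phylum for h in hits],
            "identity_count": [h.identity_count for h in hits],
            "labels": [h.label_string for h in hits],
        }
    )


def unique_peptides(hits: list[MimicryHit]) -> pd.DataFrame:
    """Report-level view deduplicated to unique (antigen, hit peptide) pairs."""
    df = hits_to_frame(hits)
    if df.empty:
        return df
    return (
        df.sort_values(["antigen_name", "identity_count"], ascending=[True, False])
        .drop_duplicates(subset=["antigen_name", "hit_sequence"])
        .reset_index(drop=True)
    )


def count_hits(hits: list[MimicryHit], predictions=None) -> pd.DataFrame:
    """Per-(antigen, phylum) totals and high-affinity (< 10 nM) counts.

    ``predictions`` maps (peptide, allele) -> affinity in nM (or is a list of
    BindingPrediction).  Without predictions the high-affinity column is 0.
    Raises if predictions are supplied but do not cover every hit peptide.
    """
    affinity: dict[tuple[str, str], float] = {}
    if predictions is not None:
        if isinstance(predictions, dict):
            affinity = dict(predictions)
        else:
            affinity = {(p.peptide, p.hla_allele): p.affinity_nm for p in predictions}
        uncovered = sorted(
            {
                (h.hit_sequence, h.epitope.hla_allele)
                for h in hits
                if (h.hit_sequence, h.epitope.hla_allele) not in affinity
            }
        )
        if uncovered:
            raise ValueError(f"predictions missing for peptides: {uncovered}")

    rows: dict[tuple[str, str], list[int]] = {}
    for h in hits:
        key = (h.epitope.antigen_name, h.phylum)
        n_total, n_high = rows.get(key, [0, 0])
        n_total += 1
        if predictions is not None:
            if affinity[(h.hit_sequence, h.epitope.hla_allele)] < HIGH_AFFINITY_NM:
                n_high += 1
        rows[key] = [n_total, n_high]

    out = pd.DataFrame(
        [
            {"antigen_name": a, "phylum": p, "n_total": t, "n_high_affinity": hi}
            for (a, p), (t, hi) in sorted(rows.items())
        ]
    )
    return out
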