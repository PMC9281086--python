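"""Alignment-population statistics.

Summaries over the set of mimicry hits for each tumor antigen: the
distribution of identity counts, per-position substitution-class percentages,
position frequency matrices with information content (sequence-logo data),
consensus/epitope agreement, and the random-stretch probability model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mimicry_core import (
    CONSERVATIVE,
    EPITOPE_LENGTH,
    IDENTICAL,
    NON_CONSERVATIVE,
    STANDARD_AA,
    EpitopeRecord,
    MimicryHit,
    _check_nonamer,
)

logger = logging.getLogger(__name__)

CATEGORIES = (IDENTICAL, CONSERVATIVE, NON_CONSERVATIVE)
MAX_BITS = math.log2(len(STANDARD_AA))  # log2 20 ~= 4.3219


# ---------------------------------------------------------------------------
# Identity-count distribution
# ---------------------------------------------------------------------------

def identity_distribution(hits: list[MimicryHit]) -> pd.DataFrame:
    """Per-antigen distribution of identity counts 0-9.

    One row per antigen with columns ``n_<k>`` / ``pct_<k>`` for k in 0..9,
    the share with 6 or 7 identical residues (``pct_6_or_7``), and the mean
    identity count.  Percentages per antigen sum to 100.
    """
    rows = []
    by_antigen: dict[str, list[int]] = {}
    for h in hits:
        by_antigen.setdefault(h.epitope.antigen_name, []).append(h.identity_count)
    for antigen, counts in sorted(by_antigen.items()):
        n = len(counts)
        row: dict[str, float | str | int] = {"antigen_name": antigen, "n_hits": n}
        for k in range(EPITOPE_LENGTH + 1):
            nk = counts.count(k)
            row[f"n_{k}"] = nk
            row[f"pct_{k}"] = 100.0 * nk / n
        row["pct_6_or_7"] = row["pct_6"] + row["pct_7"]
        row["mean_identity"] = float(np.mean(counts))
        rows.append(row)
    return pd.DataFrame(rows)


def average_6_or_7_share(dist: pd.DataFrame) -> float:
    """Cross-antigen average of the 6-or-7-identical share (percent)."""
    if dist.empty:
        raise ValueError("empty identity distribution")
    return float(dist["pct_6_or_7"].mean())


# ---------------------------------------------------------------------------
# Per-position substitution statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionStats:
    """Counts and percentages of substitution classes per peptide position.

    ``table`` has 9 rows (index ``position`` 1-based) with count and percent
    columns per category; ``averages`` maps category -> mean percent across
    the 9 positions.
    """

    table: pd.DataFrame
    averages: dict[str, float]
    n_hits: int


def per_position_stats(hits: list[MimicryHit]) -> PositionStats:
    """Category percentages at each of the 9 positions over all hits."""
    if not hits:
        raise ValueError("no hits")
    n = len(hits)
    counts = {cat: np.zeros(EPITOPE_LENGTH, dtype=int) for cat in CATEGORIES}
    for h in hits:
        for pos, lab in enumerate(h.position_labels):
            counts[lab][pos] += 1
    table = pd.DataFrame({"position": np.arange(1, EPITOPE_LENGTH + 1)})
    for cat in CATEGORIES:
        table[f"n_{cat}"] = counts[cat]
        table[f"pct_{cat}"] = 100.0 * counts[cat] / n
    table = table.set_index("position")
    averages = {cat: float(table[f"pct_{cat}"].mean()) for cat in CATEGORIES}
    return PositionStats(table=table, averages=averages, n_hits=n)


# ---------------------------------------------------------------------------
# Position frequency matrix / logo data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """9x20 relative frequencies with logo information content.

    ``frequencies`` is indexed by position (1-based) with one column per
    standard residue; rows sum to 1.  ``information_bits`` is the per-position
    stack height: log2(20) minus the Shannon entropy for a uniform background,
    or the Kullback-Leibler divergence from a non-uniform background.
    ``consensus`` is the argmax residue per position (alphabetical tie-break;
    tied positions flagged in ``consensus_ties``).
    """

    frequencies: pd.DataFrame
    information_bits: np.ndarray
    consensus: str
    consensus_ties: tuple[int, ...]  # 1-based positions with a tied argmax
    n_sequences: int

    def logo_heights(self) -> pd.DataFrame:
        """Per-residue letter heights: frequency x information content."""
        return self.frequencies.mul(self.information_bits, axis=0)


def build_pfm(
    hit_sequences: list[str], background: np.ndarray | None = None
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix from nonamer hit sequences.

    ``background`` is an optional 20-vector of residue frequencies (order of
    ``STANDARD_AA``, summing to 1); when given, information content is the KL
    divergence of each column from it rather than uniform-background Shannon
    information.
    """
    if not hit_sequences:
        raise ValueError("no sequences")
    seqs = [_check_nonamer(s) for s in hit_sequences]
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != (len(STANDARD_AA),):
            raise ValueError("background must be a 20-vector")
        if not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if (background <= 0).any():
            raise ValueError("background frequencies must be positive")

    counts = np.zeros((EPITOPE_LENGTH, len(STANDARD_AA)))
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for s in seqs:
        for pos, aa in enumerate(s):
            counts[pos, aa_index[aa]] += 1
    freqs = counts / len(seqs)

    info = np.empty(EPITOPE_LENGTH)
    for pos in range(EPITOPE_LENGTH):
        p = freqs[pos]
        nz = p > 0
        if background is None:
            entropy = float(-(p[nz] * np.log2(p[nz])).sum())
            info[pos] = MAX_BITS - entropy
        else:
            info[pos] = float((p[nz] * np.log2(p[nz] / background[nz])).sum())
        info[pos] = min(max(info[pos], 0.0), MAX_BITS)

    consensus_chars = []
    ties = []
    for pos in range(EPITOPE_LENGTH):
        best = freqs[pos].max()
        winners = [STANDARD_AA[i] for i in np.flatnonzero(freqs[pos] == best)]
        consensus_chars.append(min(winners))  # alphabetical tie-break
        if len(winners) > 1:
            ties.append(pos + 1)

    frequencies = pd.DataFrame(
        freqs, index=pd.RangeIndex(1, EPITOPE_LENGTH + 1, name="position"),
        columns=list(STANDARD_AA),
    )
    return PositionFrequencyMatrix(
        frequencies=frequencies,
        information_bits=info,
        consensus="".join(consensus_chars),
        consensus_ties=tuple(ties),
        n_sequences=len(seqs),
    )


def consensus_match(
    pfm: PositionFrequencyMatrix, epitope: EpitopeRecord | str
) -> tuple[tuple[bool, ...], bool]:
    """Does the hit-population consensus reproduce the epitope sequence?

    Returns (per-position booleans, overall flag).  Position i matches iff
    the consensus residue equals epitope residue i.
    """
    seq = epitope.sequence if isinstance(epitope, EpitopeRecord) else _check_nonamer(epitope)
    flags = tuple(c == e for c, e in zip(pfm.consensus, seq))
    return flags, all(flags)


# ---------------------------------------------------------------------------
# Random-stretch probability model
# ---------------------------------------------------------------------------

def stretch_match_probability(k: int, alphabet_size: int = 20) -> float:
    """Probability that k given positions agree between two uniform random peptides.

    The per-stretch form ``(1/alphabet_size)**k`` with no positional or
    combinatorial correction: k=6 gives 1.5625e-8 and k=9 gives 1.953125e-12
    for the 20-letter alphabet.
    """
    if not 1 <= k <= EPITOPE_LENGTH:
        raise ValueError(f"k must be in [1, 9], got {k}")
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    return (1.0 / alphabet_size) ** k


def stretch_match_probability_any_window(
    k: int, peptide_length: int = EPITOPE_LENGTH, alphabet_size: int = 20
) -> float:
    """Union-bound variant over all contiguous k-windows of the peptide.

    Multiplies the per-stretch probability by the number of possible start
    positions.  This 'any-window' correction is an extension of the plain
    per-stretch statistic, not an alternative printing of it.
    """
    p = stretch_match_probability(k, alphabet_size)
    return min(1.0, (peptide_length - k + 1) * p)
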