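"""Binding affinity / stability acquisition and threshold classification.

The analysis needs, for each peptide-allele pair, a predicted HLA class I
affinity (nM) and optionally a complex half-life (hours).  Real predictions
come from external neural-network tools and are imported as TSV tables; a
transparent position-weight-matrix (PWM) predictor is provided so the whole
pipeline can run end to end on synthetic data without downloads.

Threshold logic (class assignment):

* ``high``   — affinity < 10 nM
* ``strong`` — 10 nM <= affinity < 100 nM, and stability > 1 h when a
  stability value is available (strong binder, "SB")
* ``non``    — everything else

When stability is absent the > 1 h criterion is skipped (affinity-only SB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mimicry_core import STANDARD_AA, EPITOPE_LENGTH, MimicryHit, _check_nonamer

logger = logging.getLogger(__name__)

HIGH_NM = 10.0
STRONG_NM = 100.0
STABILITY_H = 1.0
#: Affinity ceiling of the score->nM transform (the conventional 50 kNM cap).
AFFINITY_CAP_NM = 50000.0


def binder_class(affinity_nm: float, stability_h: float | None = None) -> str:
    """Total threshold classification: every positive affinity maps to one class."""
    if affinity_nm <= 0:
        raise ValueError(f"affinity must be positive, got {affinity_nm}")
    if stability_h is not None and stability_h <= 0:
        raise ValueError(f"stability must be positive, got {stability_h}")
    if affinity_nm < HIGH_NM:
        return "high"
    if affinity_nm < STRONG_NM and (stability_h is None or stability_h > STABILITY_H):
        return "strong"
    return "non"


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    hla_allele: str
    affinity_nm: float
    stability_h: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", _check_nonamer(self.peptide, "peptide"))
        if self.affinity_nm <= 0:
            raise ValueError(f"{self.peptide}: affinity must be positive")

    @property
    def binder_class(self) -> str:
        return binder_class(self.affinity_nm, self.stability_h)


def import_predictions(path: str | Path) -> list[BindingPrediction]:
    """Read a prediction TSV with columns peptide, allele, affinity_nm[, stability_h].

    Whitespace-aligned exports are tolerated: if the tab-split header lacks
    the required columns the file is re-read with whitespace separation and
    columns matched by name.  Malformed rows raise with their line number.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"peptide", "allele", "affinity_nm"} <= set(df.columns):
        df = pd.read_csv(path, sep=r"\s+")
    missing = {"peptide", "allele", "affinity_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"prediction table {path}: missing columns {sorted(missing)}")

    out: list[BindingPrediction] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            stab = getattr(row, "stability_h", None)
            if stab is not None and pd.isna(stab):
                stab = None
            out.append(
                BindingPrediction(
                    peptide=str(row.peptide),
                    hla_allele=str(row.allele),
                    affinity_nm=float(row.affinity_nm),
                    stability_h=None if stab is None else float(stab),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return out


def export_predictions(predictions: list[BindingPrediction], path: str | Path) -> None:
    pd.DataFrame(
        {
            "peptide": [p.peptide for p in predictions],
            "allele": [p.hla_allele for p in predictions],
            "affinity_nm": [p.affinity_nm for p in predictions],
            "stability_h": [p.stability_h for p in predictions],
            "binder_class": [p.binder_class for p in predictions],
        }
    ).to_csv(path, sep="\t", index=False)


class PWMPredictor:
    """Position-weight-matrix affinity stand-in.

    The raw score of a nonamer is the sum of per-position log-odds; a clamped
    linear map sends [score_min, score_max] onto [0, 1], and affinity follows
    the standard convention ``affinity_nm = 50000 ** (1 - s)`` — s=1 gives
    1 nM, s=0 gives 50 uM.  Strictly decreasing in the normalized score.
    """

    def __init__(
        self,
        allele: str,
        log_odds: np.ndarray,
        score_min: float | None = None,
        score_max: float | None = None,
    ) -> None:
        log_odds = np.asarray(log_odds, dtype=float)
        if log_odds.shape != (EPITOPE_LENGTH, len(STANDARD_AA)):
            raise ValueError(f"log_odds must be 9x20, got {log_odds.shape}")
        self.allele = allele
        self.log_odds = log_odds
        self.score_min = float(log_odds.min(axis=1).sum() if score_min is None else score_min)
        self.score_max = float(log_odds.max(axis=1).sum() if score_max is None else score_max)
        if not self.score_max > self.score_min:
            raise ValueError("score_max must exceed score_min")
        self._aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    @classmethod
    def from_anchor_motif(
        cls, allele: str, motif: str, anchor_weight: float = 4.0, seed: int = 0
    ) -> "PWMPredictor":
        """Predictor favouring a nonamer motif, with extra weight at anchors 2/9.

        Jittered small background log-odds keep scores non-degenerate while the
        motif residues dominate; deterministic for a fixed seed.
        """
        motif = _check_nonamer(motif, "motif")
        rng = np.random.default_rng(seed)
        lo = rng.normal(0.0, 0.25, size=(EPITOPE_LENGTH, len(STANDARD_AA)))
        for pos, aa in enumerate(motif):
            w = anchor_weight * (2.0 if pos in (1, 8) else 1.0)
            lo[pos, STANDARD_AA.index(aa)] += w
        return cls(allele, lo)

    def score(self, peptide: str) -> float:
        peptide = _check_nonamer(peptide, "peptide")
        try:
            return float(
                sum(self.log_odds[pos, self._aa_index[aa]] for pos, aa in enumerate(peptide))
            )
        except KeyError as exc:  # pragma: no cover - nonamer check precedes
            raise ValueError(f"residue {exc} absent from matrix") from exc

    def normalized_score(self, peptide: str) -> float:
        s = (self.score(peptide) - self.score_min) / (self.score_max - self.score_min)
        return float(min(1.0, max(0.0, s)))

    def predict(self, peptide: str) -> BindingPrediction:
        s = self.normalized_score(peptide)
        return BindingPrediction(
            peptide=peptide,
            hla_allele=self.allele,
            affinity_nm=AFFINITY_CAP_NM ** (1.0 - s),
        )


def pwm_predict(peptide: str, predictor: PWMPredictor) -> BindingPrediction:
    """Functional alias for :meth:`PWMPredictor.predict`."""
    return predictor.predict(peptide)


def predict_hits(
    hits: list[MimicryHit], predictors: dict[str, PWMPredictor]
) -> list[BindingPrediction]:
    """PWM predictions for every unique (hit peptide, allele) pair plus each TAA."""
    pairs: dict[tuple[str, str], None] = {}
    for h in hits:
        pairs[(h.hit_sequence, h.epitope.hla_allele)] = None
        pairs[(h.epitope.sequence, h.epitope.hla_allele)] = None
    out = []
    for peptide, allele in sorted(pairs):
        if allele not in predictors:
            raise ValueError(f"no predictor for allele {allele}")
        out.append(predictors[allele].predict(peptide))
    return out


def summarize_affinity(
    hits: list[MimicryHit],
    predictions: list[BindingPrediction] | dict[tuple[str, str], float],
    unique: bool = True,
) -> pd.DataFrame:
    """Per-(antigen, phylum) affinity summary.

    Columns: ``mean_affinity_nm``, ``frac_below_mean`` (strictly below the
    group mean), ``frac_below_taa`` (strictly below the paired TAA's own
    affinity), ``n_peptides``.  Averages are over unique (antigen, peptide)
    pairs by default; set ``unique=False`` to weight by hit occurrences.
    Raises if the TAA itself has no prediction.
    """
    if isinstance(predictions, dict):
        affinity = dict(predictions)
    else:
        affinity = {(p.peptide, p.hla_allele): p.affinity_nm for p in predictions}

    groups: dict[tuple[str, str], list[float]] = {}
    taa_affinity: dict[str, float] = {}
    seen: set[tuple[str, str, str]] = set()
    for h in hits:
        allele = h.epitope.hla_allele
        taa_key = (h.epitope.sequence, allele)
        if taa_key not in affinity:
            raise ValueError(
                f"missing prediction for TAA {h.epitope.antigen_name} "
                f"({h.epitope.sequence}, {allele})"
            )
        taa_affinity[h.epitope.antigen_name] = affinity[taa_key]
        key = (h.epitope.antigen_name, h.phylum)
        dedup = (h.epitope.antigen_name, h.phylum, h.hit_sequence)
        if unique and dedup in seen:
            continue
        seen.add(dedup)
        pep_key = (h.hit_sequence, allele)
        if pep_key not in affinity:
            raise ValueError(f"missing prediction for hit peptide {pep_key}")
        groups.setdefault(key, []).append(affinity[pep_key])

    rows = []
    for (antigen, phylum), values in sorted(groups.items()):
        arr = np.asarray(values)
        mean = float(arr.mean())
        rows.append(
            {
                "antigen_name": antigen,
                "phylum": phylum,
                "n_peptides": len(arr),
                "mean_affinity_nm": mean,
                "frac_below_mean": float((arr < mean).mean()),
                "frac_below_taa": float((arr < taa_affinity[antigen]).mean()),
                "taa_affinity_nm": taa_affinity[antigen],
            }
        )
    return pd.DataFrame(rows)
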