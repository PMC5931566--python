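"""Amino-acid composition profiles and bootstrap enrichment.

Compares the pooled amino-acid composition of a query protein set against a
background set the way composition-profiling tools do: per amino acid ``a``
the relative enrichment is ``(Cq(a) - Cb(a)) / Cb(a)`` where Cq and Cb are
the pooled fractions in the query and background.  Uncertainty comes from a
protein-level bootstrap: proteins (not residues) are resampled with
replacement independently within each set, because residues within one
protein are not independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, ProteinRecord

__all__ = [
    "CompositionProfile",
    "EnrichmentResult",
    "count_matrix",
    "pooled_composition",
    "enrichment",
    "bootstrap_enrichment",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class CompositionProfile:
    """Pooled residue counts and fractions over the 20 canonical AAs."""

    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class EnrichmentResult:
    """Per-amino-acid enrichment with bootstrap CI and p-value.

    ``enrichment`` is NaN when the background fraction is zero (undefined,
    flagged rather than divided).
    """

    amino_acid: str
    query_fraction: float
    background_fraction: float
    enrichment: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


def count_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """(n_proteins, 20) residue-count matrix; X residues are excluded."""
    mat = np.zeros((len(records), 20), dtype=np.int64)
    for i, rec in enumerate(records):
        for c in rec.sequence:
            j = _AA_INDEX.get(c)
            if j is not None:
                mat[i, j] += 1
    return mat


def pooled_composition(records: Sequence[ProteinRecord]) -> CompositionProfile:
    """Pooled composition of a protein set (X excluded, renormalized)."""
    if not records:
        raise ValueError("empty protein set")
    counts = count_matrix(records).sum(axis=0)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no canonical residues in protein set (all X?)")
    return CompositionProfile(
        counts={aa: int(c) for aa, c in zip(AMINO_ACIDS, counts)},
        fractions={aa: c / total for aa, c in zip(AMINO_ACIDS, counts)},
    )


def enrichment(
    query: CompositionProfile, background: CompositionProfile
) -> dict[str, float]:
    """Point enrichment (Cq - Cb) / Cb per amino acid.

    Amino acids absent from the background get NaN (undefined) rather than
    a division by zero.
    """
    out = {}
    for aa in AMINO_ACIDS:
        cb = background.fractions[aa]
        cq = query.fractions[aa]
        out[aa] = (cq - cb) / cb if cb > 0 else float("nan")
    return out


def _bootstrap_fractions(
    counts: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, 20) pooled fractions over B protein-level resamples."""
    n = counts.shape[0]
    idx = rng.integers(0, n, size=(B, n))
    pooled = counts[idx].sum(axis=1).astype(float)
    totals = pooled.sum(axis=1, keepdims=True)
    return pooled / np.where(totals > 0, totals, 1.0)


def bootstrap_enrichment(
    query_records: Sequence[ProteinRecord],
    background_records: Sequence[ProteinRecord],
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """Bootstrap CI and significance for per-amino-acid enrichment.

    Both sets are resampled at the protein level, with replacement,
    independently, *B* times; each replicate's pooled compositions give a
    replicate enrichment.  The CI is the empirical (alpha/2, 1 - alpha/2)
    quantile interval and the two-sided p-value is the Monte-Carlo sign
    test ``2 * (min(#{rep <= 0}, #{rep >= 0}) + 1) / (B + 1)`` clipped to
    [2/(B+1), 1]; the add-one numerator is the standard finite-B correction
    that keeps the test from being anti-conservative.
    Replicates whose background count for an amino acid is zero are dropped
    for that amino acid.  Deterministic for a given *seed*.  With
    ``bonferroni=True`` the significance threshold becomes alpha / 20.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100 for stable quantiles, got {B}")
    if not query_records or not background_records:
        raise ValueError("query and background sets must be non-empty")
    q_counts = count_matrix(query_records)
    b_counts = count_matrix(background_records)
    q_prof = pooled_composition(query_records)
    b_prof = pooled_composition(background_records)
    point = enrichment(q_prof, b_prof)

    rng = np.random.default_rng(seed)
    q_reps = _bootstrap_fractions(q_counts, B, rng)
    b_reps = _bootstrap_fractions(b_counts, B, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.where(b_reps > 0, (q_reps - b_reps) / b_reps, np.nan)

    threshold = alpha / 20 if bonferroni else alpha
    results = []
    for j, aa in enumerate(AMINO_ACIDS):
        col = reps[:, j]
        valid = col[~np.isnan(col)]
        if np.isnan(point[aa]) or valid.size == 0:
            results.append(EnrichmentResult(
                aa, q_prof.fractions[aa], b_prof.fractions[aa],
                float("nan"), float("nan"), float("nan"), float("nan"),
                False,
            ))
            continue
        lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
        nb = valid.size
        p = 2.0 * (min(int(np.sum(valid <= 0)),
                       int(np.sum(valid >= 0))) + 1) / (nb + 1)
        p = min(1.0, max(2.0 / (nb + 1), p))
        results.append(EnrichmentResult(
            amino_acid=aa,
            query_fraction=q_prof.fractions[aa],
            background_fraction=b_prof.fractions[aa],
            enrichment=point[aa],
            ci_low=float(lo),
            ci_high=float(hi),
            p_value=p,
            significant=p < threshold,
        ))
    return results


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Report frame, one row per amino acid in alphabetical order."""
    return pd.DataFrame([
        {
            "amino_acid": r.amino_acid,
            "query_fraction": r.query_fraction,
            "background_fraction": r.background_fraction,
            "enrichment": r.enrichment,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in sorted(results, key=lambda r: r.amino_acid)
    ])
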