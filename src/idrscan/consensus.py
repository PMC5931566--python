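"""Protein-level IDP calling and multi-predictor consensus.

A protein is called an IDP from its per-predictor disorder summary under
one of two criteria:

strict
    longest disordered region (LDR) >= 30 consecutive residues.

extended
    the strict clause, OR an LDR in [10, 30) together with a percent
    disorder above 10 — capturing proteins whose flexibility is spread over
    shorter segments.

Predictors are then combined by k-of-n voting over a common protein
universe; with k = n (the default) a protein must be selected by every
predictor, the most conservative consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .disorder_metrics import DisorderSummary
from .seqio import ProteinRecord

__all__ = [
    "IDPCriteria",
    "call_idp",
    "idp_calls",
    "consensus_sets",
    "consensus_table",
    "intersect_with_annotation",
]


@dataclass
class IDPCriteria:
    """IDP-calling thresholds.

    ``mode`` is ``"strict"`` or ``"extended"``; ``ldr_strict`` is the long-
    region threshold (call when LDR >= ldr_strict); the extended mode adds
    proteins with ``ldr_low <= LDR < ldr_strict`` and percent disorder
    strictly above ``percent_min``.
    """

    mode: str = "extended"
    ldr_strict: int = 30
    ldr_low: int = 10
    percent_min: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "extended"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.ldr_low < self.ldr_strict:
            raise ValueError("ldr_low must be < ldr_strict")
        if self.percent_min < 0:
            raise ValueError("percent_min must be >= 0")


def call_idp(summary: DisorderSummary, criteria: IDPCriteria) -> bool:
    """Apply the IDP criteria to one (protein, predictor) summary."""
    if summary.ldr >= criteria.ldr_strict:
        return True
    if criteria.mode == "extended":
        return (criteria.ldr_low <= summary.ldr < criteria.ldr_strict
                and summary.percent_disorder > criteria.percent_min)
    return False


def idp_calls(
    summaries: Iterable[DisorderSummary], criteria: IDPCriteria
) -> dict[str, dict[str, bool]]:
    """Per-predictor, per-protein IDP calls: {predictor: {protein: bool}}."""
    calls: dict[str, dict[str, bool]] = {}
    for s in summaries:
        calls.setdefault(s.predictor, {})[s.protein_id] = call_idp(
            s, criteria)
    return calls


def _check_universes(calls: Mapping[str, Mapping[str, bool]]) -> set[str]:
    universes = {p: set(c) for p, c in calls.items()}
    first = next(iter(universes.values()))
    for pred, ids in universes.items():
        if ids != first:
            raise ValueError(
                f"predictor {pred!r} covers a different protein universe "
                f"({len(ids)} vs {len(first)} proteins)"
            )
    return first


def consensus_sets(
    calls: Mapping[str, Mapping[str, bool]], k: int | None = None
) -> set[str]:
    """Proteins called IDP by at least *k* predictors (default: all).

    All predictors must cover the same protein universe.  ``k = 1`` is the
    union of the per-predictor IDP sets; ``k = n`` their intersection.
    """
    if not calls:
        raise ValueError("no predictor calls given")
    universe = _check_universes(calls)
    n = len(calls)
    if k is None:
        k = n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    return {
        pid for pid in universe
        if sum(calls[p][pid] for p in calls) >= k
    }


def consensus_table(
    calls: Mapping[str, Mapping[str, bool]], k: int | None = None
) -> pd.DataFrame:
    """Report frame: one 0/1 column per predictor, support count, consensus."""
    universe = sorted(_check_universes(calls))
    preds = sorted(calls)
    if k is None:
        k = len(preds)
    rows = []
    for pid in universe:
        support = sum(calls[p][pid] for p in preds)
        row = {"protein_id": pid}
        row.update({p: int(calls[p][pid]) for p in preds})
        row["n_supporting"] = support
        row["consensus"] = int(support >= k)
        rows.append(row)
    return pd.DataFrame(rows)


def intersect_with_annotation(
    idp_set: Iterable[str],
    records: Sequence[ProteinRecord],
    flag: str = "phospho",
) -> tuple[set[str], float]:
    """Members of *idp_set* whose boolean annotation *flag* is true.

    Returns the subset plus its share of the source set as a percent
    (half-up, one decimal); an empty source set yields 0%.  Used e.g. to
    cross-reference an IDP set against a phosphoproteome.
    """
    idp_set = set(idp_set)
    flagged = {
        r.id for r in records
        if r.id in idp_set and bool(r.annotations.get(flag, False))
    }
    pct = (round_half_up(100.0 * len(flagged) / len(idp_set), 1)
           if idp_set else 0.0)
    return flagged, pct
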