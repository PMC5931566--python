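"""Per-protein disorder summaries: counts, percent disorder, LDR, LDR bins.

The longest disordered region (LDR) of a call track is the length of its
longest maximal run of disordered calls.  LDRs are reported both raw and
binned into the length ranges ``0~9 / 10~29 / 30~49 / 50~99 / 100<``
(the last bin meaning LDR >= 100, so the bins partition the non-negative
integers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .predictors import CallTrack
from .seqio import ProteinRecord

__all__ = [
    "BIN_LABELS",
    "DisorderSummary",
    "longest_run",
    "percent_disorder",
    "ldr_bin",
    "summarize",
    "bin_frequency_table",
    "summaries_to_frame",
]

#: LDR length-range bins, in increasing order.
BIN_LABELS: tuple[str, ...] = ("0~9", "10~29", "30~49", "50~99", "100<")

_BIN_EDGES = (10, 30, 50, 100)  # lower edges of bins 1..4


@dataclass
class DisorderSummary:
    """Disorder metrics for one (protein, predictor) pair."""

    protein_id: str
    predictor: str
    length: int
    n_disordered: int
    percent_disorder: float
    ldr: int
    ldr_bin: str


def longest_run(calls: Sequence[bool] | np.ndarray) -> int:
    """Length of the longest maximal run of True values (0 if none)."""
    arr = np.asarray(calls, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty call track")
    padded = np.concatenate([[False], arr, [False]]).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    if edges.size == 0:
        return 0
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def percent_disorder(calls: Sequence[bool] | np.ndarray) -> float:
    """100 * disordered residues / track length."""
    arr = np.asarray(calls, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty call track")
    return 100.0 * int(arr.sum()) / arr.size


def ldr_bin(ldr: int) -> str:
    """Map an LDR to its length-range bin label."""
    if ldr < 0:
        raise ValueError(f"LDR must be non-negative, got {ldr}")
    for label, edge in zip(BIN_LABELS[1:][::-1], _BIN_EDGES[::-1]):
        if ldr >= edge:
            return label
    return BIN_LABELS[0]


def summarize(
    call_tracks: Iterable[CallTrack],
    records: Sequence[ProteinRecord] | None = None,
) -> list[DisorderSummary]:
    """One :class:`DisorderSummary` per (protein, predictor) track.

    When *records* is given, every track must belong to a known protein and
    match its length; an orphan or mismatched track raises ``ValueError``.
    Output is deterministically ordered by (protein_id, predictor).
    """
    lengths = {r.id: len(r) for r in records} if records is not None else None
    out = []
    for t in sorted(call_tracks, key=lambda t: (t.protein_id, t.predictor)):
        if lengths is not None:
            if t.protein_id not in lengths:
                raise ValueError(f"track for unknown protein "
                                 f"{t.protein_id!r}")
            if len(t) != lengths[t.protein_id]:
                raise ValueError(
                    f"track ({t.protein_id!r}, {t.predictor!r}) length "
                    f"{len(t)} != protein length {lengths[t.protein_id]}"
                )
        ldr = longest_run(t.calls)
        out.append(DisorderSummary(
            protein_id=t.protein_id,
            predictor=t.predictor,
            length=len(t),
            n_disordered=int(np.sum(t.calls)),
            percent_disorder=percent_disorder(t.calls),
            ldr=ldr,
            ldr_bin=ldr_bin(ldr),
        ))
    return out


def summaries_to_frame(summaries: Iterable[DisorderSummary]) -> pd.DataFrame:
    """Tidy DataFrame view of summaries (report schema)."""
    return pd.DataFrame([
        {
            "protein_id": s.protein_id, "predictor": s.predictor,
            "length": s.length, "n_disordered": s.n_disordered,
            "percent_disorder": s.percent_disorder,
            "ldr": s.ldr, "ldr_bin": s.ldr_bin,
        }
        for s in summaries
    ])


def bin_frequency_table(
    summaries: Sequence[DisorderSummary],
    total: int | None = None,
) -> pd.DataFrame:
    """Per-predictor LDR-bin counts and percents.

    Percents are 100 * count / total, half-up rounded to one decimal;
    *total* defaults to the number of proteins seen for each predictor
    (pass it explicitly to express counts relative to a fixed universe,
    e.g. all analyzed proteins).  Returns a tidy frame with columns
    ``predictor, ldr_bin, count, percent``.
    """
    if not summaries:
        return pd.DataFrame(columns=["predictor", "ldr_bin", "count",
                                     "percent"])
    rows = []
    by_pred: dict[str, list[DisorderSummary]] = {}
    for s in summaries:
        by_pred.setdefault(s.predictor, []).append(s)
    for pred in sorted(by_pred):
        group = by_pred[pred]
        denom = total if total is not None else len(group)
        counts = {label: 0 for label in BIN_LABELS}
        for s in group:
            counts[s.ldr_bin] += 1
        for label in BIN_LABELS:
            rows.append({
                "predictor": pred,
                "ldr_bin": label,
                "count": counts[label],
                "percent": round_half_up(100.0 * counts[label] / denom, 1),
            })
    return pd.DataFrame(rows)
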