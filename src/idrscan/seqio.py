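"""Sequence, score-track and annotation I/O.

Protein sequences travel as FASTA; per-residue disorder scores (either
computed here or imported from external predictors such as PONDR VL-XT or
DisEMBL, whose models cannot be re-run locally) travel as four-column TSV
tracks; record-level annotations (subcellular compartment, GO molecular
function, phosphorylation, PSM counts, partial-sequence flags) travel as a
TSV keyed by protein id.

All per-residue positions in files are 1-based and contiguous.  Sequences
are restricted to the 20 canonical amino acids plus ``X`` (unknown);
anything else is rejected at parse time with the offending record and
position named.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "COMPARTMENTS",
    "ParseError",
    "ProteinRecord",
    "ScoreTrack",
    "read_fasta",
    "write_fasta",
    "read_score_table",
    "write_score_table",
    "read_annotations",
    "filter_records",
]

log = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted in sequences (canonical + ambiguous X).
ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | {"X"}

#: Valid subcellular compartment codes: chloroplast, mitochondrion, other.
COMPARTMENTS: frozenset[str] = frozenset("CMO")

_BOOL_STRINGS = {
    "1": True, "0": False,
    "true": True, "false": False,
    "yes": True, "no": False,
}


class ParseError(ValueError):
    """Raised on malformed FASTA/TSV input (bad residue, bad schema...)."""


@dataclass
class ProteinRecord:
    """One protein: id, sequence and optional record-level annotations.

    Annotation keys used by the pipeline: ``compartment`` (one of C/M/O),
    ``go_terms`` (list of strings), ``phospho`` (bool), ``psm``
    (non-negative int), ``partial`` (bool).  Missing annotations are simply
    absent from the mapping.
    """

    id: str
    sequence: str
    description: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            pos = next(
                i + 1 for i, c in enumerate(self.sequence) if c in bad
            )
            raise ParseError(
                f"record {self.id!r}: illegal residue "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """Per-residue real-valued disorder scores for one (protein, predictor).

    ``scores[i]`` is the score of residue at 1-based position ``i + 1``.
    """

    protein_id: str
    predictor: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ParseError(
                f"track ({self.protein_id!r}, {self.predictor!r}): "
                "scores must be a non-empty 1-D sequence"
            )

    def __len__(self) -> int:
        return self.scores.size


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    The header token up to the first whitespace is the id; the remainder is
    the description.  Sequences are uppercased.  Duplicate ids and residues
    outside the 21-letter alphabet raise :class:`ParseError`.  An empty file
    yields an empty list (with a logged warning).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        desc = entry.description[len(entry.id):].strip()
        records.append(
            ProteinRecord(id=entry.id, sequence=str(entry.seq),
                          description=" ".join(desc.split()))
        )
    if not records:
        log.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapped)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


_SCORE_COLUMNS = ["protein_id", "predictor", "position", "score"]


def read_score_table(
    path: str | Path,
    records: Sequence[ProteinRecord] | None = None,
) -> list[ScoreTrack]:
    """Read per-residue score tracks from TSV.

    Expects columns ``protein_id, predictor, position, score`` with a header
    row.  Rows are grouped per (protein_id, predictor); within each group
    positions must be exactly 1..L with no gap or duplicate.  When *records*
    is given, each track's length is checked against its protein.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    lengths = {r.id: len(r) for r in records} if records is not None else None
    tracks: list[ScoreTrack] = []
    for (pid, pred), grp in df.groupby(["protein_id", "predictor"],
                                       sort=True):
        pos = np.sort(grp["position"].to_numpy(dtype=int))
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            raise ParseError(
                f"{path}: positions for ({pid!r}, {pred!r}) are not "
                f"contiguous 1..{len(pos)}"
            )
        scores = (
            grp.sort_values("position")["score"].to_numpy(dtype=float)
        )
        if lengths is not None:
            if pid not in lengths:
                raise ParseError(f"{path}: track for unknown protein {pid!r}")
            if len(scores) != lengths[pid]:
                raise ParseError(
                    f"{path}: track ({pid!r}, {pred!r}) has {len(scores)} "
                    f"positions but protein has {lengths[pid]} residues"
                )
        tracks.append(ScoreTrack(str(pid), str(pred), scores))
    return tracks


def write_score_table(
    tracks: Iterable[ScoreTrack], path: str | Path
) -> None:
    """Write tracks in the :func:`read_score_table` schema (round-trips)."""
    frames = []
    for t in sorted(tracks, key=lambda t: (t.protein_id, t.predictor)):
        frames.append(pd.DataFrame({
            "protein_id": t.protein_id,
            "predictor": t.predictor,
            "position": np.arange(1, len(t) + 1),
            "score": t.scores,
        }))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=_SCORE_COLUMNS))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotations(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach annotation columns from a TSV keyed by ``protein_id``.

    Recognised optional columns: ``compartment`` (C/M/O), ``go_terms``
    (semicolon-separated), ``phospho`` (boolean-ish), ``psm`` (int),
    ``partial`` (boolean-ish).  Rows whose id is absent from *records* are
    skipped with a warning; ids absent from the table keep whatever
    annotations they already carry.  Records are annotated in place and the
    same list is returned.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'protein_id'")
    by_id = {r.id: r for r in records}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        rec = by_id.get(pid)
        if rec is None:
            log.warning("%s: annotation row for unknown protein %r skipped",
                        path, pid)
            continue
        ann = rec.annotations
        if _present(row, "compartment"):
            code = row["compartment"].strip().upper()
            if code not in COMPARTMENTS:
                raise ParseError(
                    f"{path}: unknown compartment code {code!r} for {pid!r}"
                )
            ann["compartment"] = code
        if _present(row, "go_terms"):
            ann["go_terms"] = [
                t.strip() for t in row["go_terms"].split(";") if t.strip()
            ]
        if _present(row, "phospho"):
            ann["phospho"] = _parse_bool(row["phospho"], path, pid, "phospho")
        if _present(row, "psm"):
            psm = int(row["psm"])
            if psm < 0:
                raise ParseError(f"{path}: negative psm for {pid!r}")
            ann["psm"] = psm
        if _present(row, "partial"):
            ann["partial"] = _parse_bool(row["partial"], path, pid, "partial")
    return list(records)


def _present(row: pd.Series, col: str) -> bool:
    return col in row.index and isinstance(row[col], str) and row[col] != ""


def _parse_bool(value: str, path: Path, pid: str, col: str) -> bool:
    try:
        return _BOOL_STRINGS[value.strip().lower()]
    except KeyError:
        raise ParseError(
            f"{path}: cannot parse {col}={value!r} for {pid!r} as boolean"
        ) from None


def filter_records(
    records: Sequence[ProteinRecord],
    min_psm: int = 0,
    exclude_partial: bool = True,
) -> list[ProteinRecord]:
    """Apply the MS-level record filters: PSM floor and partial-sequence drop.

    Records lacking a ``psm`` annotation are treated as passing any PSM floor
    (psm = +inf); records lacking ``partial`` are treated as full-length.
    The filters therefore only act on explicit flags, so proteomes without
    MS metadata pass through unchanged.  Order-preserving and idempotent.
    """
    kept = []
    for r in records:
        psm = r.annotations.get("psm", math.inf)
        partial = r.annotations.get("partial", False)
        if psm >= min_psm and not (exclude_partial and partial):
            kept.append(r)
    return kept
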