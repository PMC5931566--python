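"""Seed-reproducible synthetic proteomes with planted disordered regions.

Each synthetic protein is a backbone of residues drawn i.i.d. from an
"ordered" amino-acid composition, into which 0 or more non-overlapping,
non-adjacent regions of residues drawn from a "disordered" composition are
planted.  Because planted regions are separated by at least one backbone
residue, the ground-truth longest disordered region of a protein is exactly
the length of its longest planted region, keeping truth analytic.

The packaged default design (``disorder_biased_spec``) biases the disordered
composition the way disordered sequence sets are biased against globular
ones (E, K, G, A, S, P up; C, W, F, Y and branched hydrophobics down) and
plants enough region mass for ~20% mean disorder per proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .disorder_metrics import DisorderSummary, summarize
from .predictors import CallTrack
from .seqio import AMINO_ACIDS, ProteinRecord, ScoreTrack

__all__ = [
    "SyntheticSpec",
    "TruthTrack",
    "disorder_biased_spec",
    "generate",
    "truth_to_call_tracks",
    "truth_summary",
    "truth_score_tracks",
]

_PLACEMENT_TRIES = 1000


@dataclass
class SyntheticSpec:
    """Design of a synthetic proteome.

    Lengths, regions per protein and region lengths are uniform integer
    draws over inclusive ranges (a fixed value is a range with min == max;
    ``regions`` may include 0).  Compositions are probability vectors over
    :data:`~idrscan.seqio.AMINO_ACIDS` order and must sum to 1.
    """

    n_proteins: int
    length: tuple[int, int]
    regions_per_protein: tuple[int, int]
    region_length: tuple[int, int]
    ordered_composition: np.ndarray
    disordered_composition: np.ndarray
    seed: int
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        self.ordered_composition = np.asarray(self.ordered_composition,
                                              dtype=float)
        self.disordered_composition = np.asarray(
            self.disordered_composition, dtype=float)
        for name, comp in (("ordered", self.ordered_composition),
                           ("disordered", self.disordered_composition)):
            if comp.shape != (20,):
                raise ValueError(f"{name}_composition must have 20 entries")
            if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name}_composition must be a probability "
                                 "vector summing to 1")
        for name, rng_ in (("length", self.length),
                           ("regions_per_protein", self.regions_per_protein),
                           ("region_length", self.region_length)):
            lo, hi = rng_
            if lo > hi or lo < 0:
                raise ValueError(f"invalid {name} range {rng_}")
        if self.length[0] < 1 or self.n_proteins < 1:
            raise ValueError("need at least one protein of length >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SyntheticSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        spec = cls(
            n_proteins=int(cfg["n_proteins"]),
            length=(int(cfg["length_min"]), int(cfg["length_max"])),
            regions_per_protein=(int(cfg["regions_min"]),
                                 int(cfg["regions_max"])),
            region_length=(int(cfg["region_length_min"]),
                           int(cfg["region_length_max"])),
            ordered_composition=np.array(
                [cfg["ordered_composition"][a] for a in AMINO_ACIDS]),
            disordered_composition=np.array(
                [cfg["disordered_composition"][a] for a in AMINO_ACIDS]),
            seed=int(cfg["seed"]),
        )
        return replace(spec, **overrides) if overrides else spec


@dataclass
class TruthTrack:
    """Ground-truth per-residue disorder labels for one synthetic protein."""

    protein_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return self.labels.size


def disorder_biased_spec(**overrides) -> SyntheticSpec:
    """The packaged default proteome design (see ``data/disorder_biased.yaml``).

    Keyword overrides replace individual fields, e.g.
    ``disorder_biased_spec(seed=7, regions_per_protein=(0, 0))`` for a
    region-free null proteome with the same compositions.
    """
    ref = resources.files("idrscan.data") / "disorder_biased.yaml"
    with resources.as_file(ref) as path:
        return SyntheticSpec.from_yaml(path, **overrides)


def _place_regions(
    length: int, region_lengths: Sequence[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping, non-adjacent [start, end) placements, or raise."""
    if not region_lengths:
        return []
    for _ in range(_PLACEMENT_TRIES):
        placements = []
        ok = True
        for rl in region_lengths:
            if rl > length:
                ok = False
                break
            start = int(rng.integers(0, length - rl + 1))
            placements.append((start, start + rl))
        if not ok:
            break
        placements.sort()
        if all(placements[i + 1][0] - placements[i][1] >= 1
               for i in range(len(placements) - 1)):
            return placements
    raise ValueError(
        f"could not place regions {list(region_lengths)} in a protein of "
        f"length {length} after {_PLACEMENT_TRIES} tries; use smaller or "
        "fewer regions"
    )


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[TruthTrack]]:
    """Generate a proteome and its ground truth from a design.

    Deterministic: identical spec (including seed) gives byte-identical
    sequences.  Each protein draws its length, its number of regions and
    their lengths, places the regions uniformly at random with >= 1 backbone
    residue between them (rejection sampling, capped), then samples region
    residues from the disordered composition and the rest from the ordered
    composition.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    width = len(str(spec.n_proteins))
    records, truths = [], []
    for i in range(spec.n_proteins):
        L = int(rng.integers(spec.length[0], spec.length[1] + 1))
        k = int(rng.integers(spec.regions_per_protein[0],
                             spec.regions_per_protein[1] + 1))
        region_lengths = [
            int(rng.integers(spec.region_length[0],
                             spec.region_length[1] + 1))
            for _ in range(k)
        ]
        placements = _place_regions(L, region_lengths, rng)
        seq = rng.choice(aa, size=L, p=spec.ordered_composition)
        labels = np.zeros(L, dtype=bool)
        for start, end in placements:
            seq[start:end] = rng.choice(
                aa, size=end - start, p=spec.disordered_composition)
            labels[start:end] = True
        pid = f"{spec.id_prefix}{i + 1:0{width}d}"
        records.append(ProteinRecord(
            id=pid, sequence="".join(seq),
            description=f"synthetic protein, {len(placements)} planted "
                        "disordered region(s)",
        ))
        truths.append(TruthTrack(pid, labels))
    return records, truths


def truth_to_call_tracks(truths: Sequence[TruthTrack]) -> list[CallTrack]:
    """View ground-truth labels as call tracks of the 'truth' predictor."""
    return [CallTrack(t.protein_id, "truth", t.labels) for t in truths]


def truth_summary(truths: Sequence[TruthTrack]) -> list[DisorderSummary]:
    """Disorder summaries of the ground truth (predictor = 'truth')."""
    return summarize(truth_to_call_tracks(truths))


def truth_score_tracks(truths: Sequence[TruthTrack]) -> list[ScoreTrack]:
    """Truth labels as 0/1 score tracks (for the score-table TSV schema)."""
    return [ScoreTrack(t.protein_id, "truth", t.labels.astype(float))
            for t in truths]
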