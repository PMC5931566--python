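"""Self-contained per-residue disorder predictors and track binarization.

Two predictor families with published, re-implementable algorithms are
provided:

``charge_hydropathy``
    A FoldIndex-style unfoldability score.  Over a sliding window the mean
    rescaled Kyte-Doolittle hydropathy <H> and mean net charge <q> are
    combined as ``2.785*<H> - |<q>| - 1.151``; negative values predict
    disorder.  The constants define the order/disorder boundary line in the
    charge-hydropathy plane.

``pairwise_energy``
    An IUPred-style estimated-energy score.  Each residue's interaction
    energy with its sequential context is estimated from a symmetric 20x20
    amino-acid propensity matrix and the window composition, then mapped
    through a logistic to a disorder probability in (0, 1); values at or
    above 0.5 predict disorder.

Neural-network predictors (PONDR VL-XT, DisEMBL) have unavailable weights
and enter the pipeline only as imported score tracks
(:func:`idrscan.seqio.read_score_table`).

Window ends are handled by truncation: no residues are invented beyond the
termini.  Ambiguous ``X`` residues are excluded from window statistics,
which are renormalized over the non-X residues present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .seqio import AMINO_ACIDS, ParseError, ProteinRecord, ScoreTrack

__all__ = [
    "KYTE_DOOLITTLE",
    "rescale_hydropathy",
    "default_charge_rule",
    "ChargeHydropathyParams",
    "EnergyModelParams",
    "CallTrack",
    "charge_hydropathy_score",
    "pairwise_energy_score",
    "binarize",
    "default_energy_params",
    "score_proteome",
    "call_tracks",
    "DEFAULT_CALL_RULES",
]

#: Kyte-Doolittle hydropathy, raw scale (Ile +4.5 ... Arg -4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def rescale_hydropathy(scale: Mapping[str, float]) -> dict[str, float]:
    """Affinely rescale a hydropathy scale to [0, 1] (min -> 0, max -> 1)."""
    lo, hi = min(scale.values()), max(scale.values())
    return {aa: (h - lo) / (hi - lo) for aa, h in scale.items()}


def default_charge_rule(histidine_charge: int = 0) -> dict[str, int]:
    """Unit charges at working pH: K, R = +1; D, E = -1; others 0.

    Histidine is near-neutral at the (unspecified) working pH and defaults
    to 0; pass ``histidine_charge=1`` to treat it as basic.
    """
    rule = {aa: 0 for aa in AMINO_ACIDS}
    rule.update({"K": 1, "R": 1, "D": -1, "E": -1, "H": histidine_charge})
    return rule


def _check_window(window: int, minimum: int = 1) -> None:
    if window < minimum or window % 2 == 0:
        raise ValueError(
            f"window must be an odd integer >= {minimum}, got {window}"
        )


@dataclass
class ChargeHydropathyParams:
    """Parameters of the charge-hydropathy (unfoldability) predictor.

    ``hydropathy`` must already be rescaled to [0, 1].  The default window
    of 51 residues follows the common FoldIndex convention.
    """

    window: int = 51
    hydropathy: dict[str, float] = field(
        default_factory=lambda: rescale_hydropathy(KYTE_DOOLITTLE))
    charge: dict[str, int] = field(default_factory=default_charge_rule)
    coef_h: float = 2.785
    coef_q: float = 1.0
    intercept: float = 1.151

    def __post_init__(self) -> None:
        _check_window(self.window)
        vals = self.hydropathy.values()
        if min(vals) < -1e-9 or max(vals) > 1 + 1e-9:
            raise ValueError("hydropathy scale must be rescaled to [0, 1]")
        if set(self.charge.values()) - {-1, 0, 1}:
            raise ValueError("charge rule values must be in {-1, 0, +1}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChargeHydropathyParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "hydropathy" in cfg and cfg.pop("rescale", False):
            cfg["hydropathy"] = rescale_hydropathy(cfg["hydropathy"])
        return cls(**cfg)


@dataclass
class EnergyModelParams:
    """Parameters of the pairwise-energy predictor.

    ``matrix`` is a symmetric 20x20 interaction-propensity matrix indexed by
    :data:`~idrscan.seqio.AMINO_ACIDS` order; higher estimated energy means
    more disorder-prone.  The logistic transform maps energies to (0, 1)
    with inflection at ``midpoint`` and steepness ``1/slope``.
    """

    matrix: np.ndarray
    window: int = 21
    midpoint: float = 0.0
    slope: float = 0.1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, 20):
            raise ValueError("energy matrix must be 20x20 in "
                             f"{AMINO_ACIDS} order")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("energy matrix must be symmetric")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        _check_window(self.window, minimum=3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyModelParams":
        """Load from YAML: ``matrix`` as {aa: {aa: value}} plus scalars."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        raw = cfg.pop("matrix")
        m = np.array([[float(raw[a][b]) for b in AMINO_ACIDS]
                      for a in AMINO_ACIDS])
        return cls(matrix=m, **cfg)


def default_energy_params() -> EnergyModelParams:
    """The packaged default energy model (see ``data/energy_matrix.yaml``)."""
    ref = resources.files("idrscan.data") / "energy_matrix.yaml"
    with resources.as_file(ref) as path:
        return EnergyModelParams.from_yaml(path)


@dataclass
class CallTrack:
    """Binary order/disorder calls for one (protein, predictor).

    ``calls[i]`` is True when the residue at 1-based position ``i + 1`` is
    called disordered.
    """

    protein_id: str
    predictor: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.ndim != 1 or self.calls.size == 0:
            raise ParseError(
                f"call track ({self.protein_id!r}, {self.predictor!r}): "
                "calls must be a non-empty 1-D sequence"
            )

    def __len__(self) -> int:
        return self.calls.size


def _window_bounds(length: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """[lo, hi) bounds of the truncated window centred at each position."""
    half = window // 2
    idx = np.arange(length)
    return np.maximum(0, idx - half), np.minimum(length, idx + half + 1)


def _window_sums(values: np.ndarray, window: int) -> np.ndarray:
    """Sliding truncated-window sums along axis 0 (values may be 2-D)."""
    csum = np.concatenate(
        [np.zeros((1,) + values.shape[1:]), np.cumsum(values, axis=0)]
    )
    lo, hi = _window_bounds(values.shape[0], window)
    return csum[hi] - csum[lo]


def charge_hydropathy_score(
    record: ProteinRecord, params: ChargeHydropathyParams | None = None
) -> ScoreTrack:
    """FoldIndex-style unfoldability score per residue.

    For each residue the window centred on it (truncated at the termini) is
    summarised by the mean rescaled hydropathy <H> and mean charge <q> of
    its non-X residues, and scored as
    ``coef_h*<H> - coef_q*|<q>| - intercept``.  Negative scores predict
    disorder.  A window containing only X residues scores ``-intercept``.
    """
    params = params or ChargeHydropathyParams()
    seq = record.sequence
    h = np.array([params.hydropathy.get(c, 0.0) for c in seq])
    q = np.array([params.charge.get(c, 0) for c in seq], dtype=float)
    valid = np.array([c != "X" for c in seq], dtype=float)
    n = _window_sums(valid, params.window)
    denom = np.where(n > 0, n, 1.0)
    mean_h = _window_sums(h * valid, params.window) / denom
    mean_q = _window_sums(q * valid, params.window) / denom
    scores = (params.coef_h * mean_h
              - params.coef_q * np.abs(mean_q)
              - params.intercept)
    return ScoreTrack(record.id, "charge_hydropathy", scores)


def pairwise_energy_score(
    record: ProteinRecord, params: EnergyModelParams | None = None
) -> ScoreTrack:
    """IUPred-style estimated-energy disorder score per residue.

    For residue i with amino acid a, the context is the truncated window
    centred at i excluding position i; its non-X composition f gives the
    estimated energy ``e_i = sum_b matrix[a][b] * f(b)``, mapped to
    ``score_i = 1 / (1 + exp((e_i - midpoint) / (-slope)))`` so that
    higher energy means a score closer to 1 (more disordered).  An X at the
    centre is scored with the composition-averaged row ``f' M f``; an empty
    context (all-X neighbours) yields e_i = 0.
    """
    params = params or default_energy_params()
    seq = record.sequence
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    L = len(seq)
    onehot = np.zeros((L, 20))
    centre = np.full(L, -1)
    for i, c in enumerate(seq):
        k = aa_index.get(c, -1)
        centre[i] = k
        if k >= 0:
            onehot[i, k] = 1.0
    counts = _window_sums(onehot, params.window) - onehot
    n_ctx = counts.sum(axis=1)
    f = counts / np.where(n_ctx > 0, n_ctx, 1.0)[:, None]
    rows = np.where(
        (centre >= 0)[:, None],
        params.matrix[np.maximum(centre, 0)],
        f @ params.matrix,  # X centre: context-averaged row
    )
    energy = np.einsum("ij,ij->i", rows, f)
    scores = 1.0 / (1.0 + np.exp((energy - params.midpoint) / -params.slope))
    return ScoreTrack(record.id, "pairwise_energy", scores)


_DIRECTIONS = ("disordered_if_below", "disordered_if_at_or_above")


def binarize(
    track: ScoreTrack, threshold: float, direction: str
) -> CallTrack:
    """Binarize a score track into order/disorder calls.

    ``disordered_if_below`` suits unfoldability scores (ties at the
    threshold are ordered); ``disordered_if_at_or_above`` suits
    probability-like scores (ties are disordered).
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if direction == "disordered_if_below":
        calls = track.scores < threshold
    else:
        calls = track.scores >= threshold
    return CallTrack(track.protein_id, track.predictor, calls)


#: Canonical binarization rule per built-in predictor:
#: (threshold, direction).
DEFAULT_CALL_RULES: dict[str, tuple[float, str]] = {
    "charge_hydropathy": (0.0, "disordered_if_below"),
    "pairwise_energy": (0.5, "disordered_if_at_or_above"),
}


def score_proteome(
    records: Iterable[ProteinRecord],
    ch_params: ChargeHydropathyParams | None = None,
    energy_params: EnergyModelParams | None = None,
) -> list[ScoreTrack]:
    """Run both built-in predictors over a proteome."""
    ch_params = ch_params or ChargeHydropathyParams()
    energy_params = energy_params or default_energy_params()
    tracks: list[ScoreTrack] = []
    for rec in records:
        tracks.append(charge_hydropathy_score(rec, ch_params))
        tracks.append(pairwise_energy_score(rec, energy_params))
    return tracks


def call_tracks(
    score_tracks: Iterable[ScoreTrack],
    rules: Mapping[str, tuple[float, str]] | None = None,
) -> list[CallTrack]:
    """Binarize tracks using per-predictor rules.

    *rules* maps predictor name to (threshold, direction); defaults to
    :data:`DEFAULT_CALL_RULES`.  Tracks from predictors without a rule
    raise ``KeyError`` (imported tracks need an explicit rule).
    """
    rules = dict(DEFAULT_CALL_RULES if rules is None else rules)
    out = []
    for t in score_tracks:
        threshold, direction = rules[t.predictor]
        out.append(binarize(t, threshold, direction))
    return out
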