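"""Proteome-level descriptive statistics.

Covers the physico-chemical and distributional summaries used to
characterize a heat-resistant proteome: theoretical isoelectric point (pI,
the pH of zero Henderson-Hasselbalch net charge) and average molecular
weight per protein; the linear relationship between a protein's number of
disordered residues (DR) and its length; treatment-yield percentages; and
frequency tables over categorical annotations (subcellular compartment, GO
molecular-function terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up
from .seqio import AMINO_ACIDS, ProteinRecord

__all__ = [
    "PkaTable",
    "default_pka_table",
    "MassTable",
    "default_mass_table",
    "net_charge",
    "theoretical_pI",
    "molecular_weight",
    "physchem_table",
    "RegressionResult",
    "dr_length_regression",
    "dr_from_percent",
    "yield_percent",
    "frequency_by_category",
]

_POSITIVE_GROUPS = ("K", "R", "H")  # plus the N-terminus
_NEGATIVE_GROUPS = ("D", "E", "C", "Y")  # plus the C-terminus


@dataclass
class PkaTable:
    """pKa values for the termini and ionizable side chains."""

    n_term: float
    c_term: float
    side_chains: dict[str, float]

    def __post_init__(self) -> None:
        required = set(_POSITIVE_GROUPS + _NEGATIVE_GROUPS) - {"H"}
        missing = required - set(self.side_chains)
        # H may be omitted only if deliberately treated as non-ionizable
        if missing - {"H"}:
            raise ValueError(f"pKa table missing side chains: "
                             f"{sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PkaTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(n_term=float(cfg["n_term"]), c_term=float(cfg["c_term"]),
                   side_chains={k: float(v)
                                for k, v in cfg["side_chains"].items()})


def default_pka_table() -> PkaTable:
    """The packaged Bjellqvist-style pKa table."""
    ref = resources.files("idrscan.data") / "pka_bjellqvist.yaml"
    with resources.as_file(ref) as path:
        return PkaTable.from_yaml(path)


@dataclass
class MassTable:
    """Average residue masses (monomer minus water) plus the water mass."""

    residues: dict[str, float]
    water: float = 18.01524
    x_mass: float | None = None  # placeholder for X; default mean of 20

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.residues)
        if missing:
            raise ValueError(f"mass table missing residues: "
                             f"{sorted(missing)}")
        if self.x_mass is None:
            self.x_mass = float(np.mean([self.residues[a]
                                         for a in AMINO_ACIDS]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MassTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(residues={k: float(v)
                             for k, v in cfg["residues"].items()},
                   water=float(cfg.get("water", 18.01524)),
                   x_mass=cfg.get("x_mass"))


def default_mass_table() -> MassTable:
    """The packaged average residue-mass table."""
    ref = resources.files("idrscan.data") / "residue_masses.yaml"
    with resources.as_file(ref) as path:
        return MassTable.from_yaml(path)


def net_charge(sequence: str, pH: float, pka: PkaTable) -> float:
    """Henderson-Hasselbalch net charge of a sequence at a given pH.

    Basic groups (N-terminus, K, R, and H when present in the table)
    contribute ``+1 / (1 + 10^(pH - pKa))``; acidic groups (C-terminus, D,
    E, C, Y) contribute ``-1 / (1 + 10^(pKa - pH))``.
    """
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in sequence:
        pk = pka.side_chains.get(aa)
        if pk is None:
            continue
        if aa in _POSITIVE_GROUPS:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pk))
        elif aa in _NEGATIVE_GROUPS:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    return charge


def theoretical_pI(
    record: ProteinRecord | str,
    pka: PkaTable | None = None,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> float:
    """Theoretical pI by bisection on pH in [0, 14].

    Net charge is monotonically decreasing in pH, so bisection converges.
    The interval is halved until it is narrower than 1e-9 pH units (at most
    *max_iter* = 60 halvings), which leaves |charge| well below *tol* at
    the returned pH; *tol* is also checked as an early exit.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    pka = pka or default_pka_table()
    lo, hi = 0.0, 14.0
    pH = 7.0
    for _ in range(max_iter):
        pH = (lo + hi) / 2.0
        c = net_charge(seq, pH, pka)
        if hi - lo < 1e-9 and abs(c) < tol:
            break
        if c > 0:
            lo = pH
        else:
            hi = pH
    return pH


def molecular_weight(
    record: ProteinRecord | str, masses: MassTable | None = None
) -> float:
    """Average molecular weight: sum of residue masses plus one water.

    X residues contribute the table's placeholder mass (default: the mean
    of the 20 canonical residue masses).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    masses = masses or default_mass_table()
    total = masses.water
    for aa in seq:
        total += masses.residues.get(aa, masses.x_mass)
    return total


def physchem_table(
    records: Sequence[ProteinRecord],
    pka: PkaTable | None = None,
    masses: MassTable | None = None,
) -> pd.DataFrame:
    """Per-protein pI and Mw report frame (columns protein_id, pI, mw)."""
    pka = pka or default_pka_table()
    masses = masses or default_mass_table()
    return pd.DataFrame([
        {"protein_id": r.id,
         "pI": theoretical_pI(r, pka),
         "mw": molecular_weight(r, masses)}
        for r in records
    ])


@dataclass
class RegressionResult:
    """Least-squares fit of disordered residues (DR) against length."""

    slope: float
    intercept: float  # 0.0 when fitted through the origin
    r_squared: float
    n: int
    through_origin: bool


def dr_from_percent(percent: float, length: int) -> int:
    """Disordered-residue count reconstructed from a percent disorder."""
    return int(round(percent * length / 100.0))


def dr_length_regression(
    points: Sequence[tuple[float, float]],
    through_origin: bool = False,
) -> RegressionResult:
    """Least-squares regression of DR on protein length.

    *points* are (length, DR) pairs.  With ``through_origin=True`` the
    model is DR = a*L (no intercept) and R^2 is computed against the
    uncentred total sum of squares, the standard convention for
    through-origin fits; otherwise an ordinary fit with intercept, R^2
    against the centred total.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (length, DR) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(np.dot(y, y))
    else:
        if np.ptp(x) == 0:
            raise ValueError("degenerate x: all lengths equal")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(float(slope), float(intercept), r2,
                            len(x), through_origin)


def yield_percent(treated_mg: float, control_mg: float) -> float:
    """Treatment yield: 100 * treated / control, half-up to one decimal."""
    if control_mg <= 0:
        raise ValueError("control amount must be positive")
    return round_half_up(100.0 * treated_mg / control_mg, 1)


def frequency_by_category(
    records: Sequence[ProteinRecord],
    key: str = "compartment",
    id_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Category counts and percents over a protein set.

    ``key="compartment"`` counts each protein once (percents over a fully
    annotated set sum to 100); ``key="go_terms"`` counts a protein once per
    term it carries, so percents may sum past 100.  Percents are relative
    to the set size (after optional restriction to *id_subset*), half-up
    rounded to one decimal.  Returns columns ``category, count, percent``.
    """
    if key not in ("compartment", "go_terms"):
        raise ValueError(f"unknown category key {key!r}")
    subset = [r for r in records
              if id_subset is None or r.id in set(id_subset)]
    n = len(subset)
    counts: dict[str, int] = {}
    for r in subset:
        if key == "compartment":
            cat = r.annotations.get("compartment")
            if cat is not None:
                counts[cat] = counts.get(cat, 0) + 1
        else:
            for term in r.annotations.get("go_terms", []):
                counts[term] = counts.get(term, 0) + 1
    return pd.DataFrame([
        {"category": cat, "count": c,
         "percent": round_half_up(100.0 * c / n, 1) if n else 0.0}
        for cat, c in sorted(counts.items())
    ], columns=["category", "count", "percent"])
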