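"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use direct Python loops (no
vectorization, no calls into the package's scoring code paths) so they can
serve as independent references for the sliding-window predictors and the
run-length metric.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idrscan.seqio import AMINO_ACIDS, ProteinRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def brute_charge_hydropathy(seq, hydropathy, charge, coef_h=2.785,
                            coef_q=1.0, intercept=1.151, window=51):
    """Direct-loop reference for the charge-hydropathy score."""
    half = window // 2
    scores = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        residues = [c for c in seq[lo:hi] if c != "X"]
        if residues:
            mean_h = sum(hydropathy[c] for c in residues) / len(residues)
            mean_q = sum(charge[c] for c in residues) / len(residues)
        else:
            mean_h = mean_q = 0.0
        scores.append(coef_h * mean_h - coef_q * abs(mean_q) - intercept)
    return scores


def brute_pairwise_energy(seq, matrix, window, midpoint, slope):
    """Direct-loop reference for the pairwise-energy score.

    *matrix* is indexed by amino-acid letters: matrix[a][b] -> float.
    """
    import math

    half = window // 2
    scores = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        context = [seq[j] for j in range(lo, hi) if j != i and seq[j] != "X"]
        n = len(context)
        freqs = {}
        for c in context:
            freqs[c] = freqs.get(c, 0) + 1
        a = seq[i]
        if n == 0:
            e = 0.0
        elif a == "X":
            # context-averaged row
            e = sum(
                (cnt1 / n) * (cnt2 / n) * matrix[b1][b2]
                for b1, cnt1 in freqs.items()
                for b2, cnt2 in freqs.items()
            )
        else:
            e = sum(matrix[a][b] * cnt / n for b, cnt in freqs.items())
        scores.append(1.0 / (1.0 + math.exp((e - midpoint) / -slope)))
    return scores


def brute_longest_run(calls):
    """Enumerate all (start, end) windows; max length of an all-True one."""
    calls = list(calls)
    best = 0
    for start in range(len(calls)):
        for end in range(start + 1, len(calls) + 1):
            if all(calls[start:end]):
                best = max(best, end - start)
    return best


def random_protein(rng, length, alphabet=AMINO_ACIDS + "X",
                   x_prob=0.0) -> str:
    letters = list(alphabet)
    if x_prob > 0:
        p = [(1 - x_prob) / (len(letters) - 1)] * len(letters)
        p[letters.index("X")] = x_prob
        return "".join(rng.choice(letters, size=length, p=p))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# --------------------------------------------------------------- fixtures


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("p1", "MKKK", description="first"),
        ProteinRecord("p2", "GGG", description="second"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def composition_vector(**fractions) -> np.ndarray:
    """20-vector over AMINO_ACIDS order from keyword fractions."""
    v = np.zeros(20)
    for aa, p in fractions.items():
        v[AMINO_ACIDS.index(aa)] = p
    return v
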