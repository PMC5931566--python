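"""Charge-hydropathy and pairwise-energy predictors, binarization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import (
    brute_charge_hydropathy,
    brute_pairwise_energy,
    random_protein,
)
from idrscan.seqio import AMINO_ACIDS, ProteinRecord
from idrscan.predictors import (
    DEFAULT_CALL_RULES,
    ChargeHydropathyParams,
    EnergyModelParams,
    KYTE_DOOLITTLE,
    binarize,
    call_tracks,
    charge_hydropathy_score,
    default_charge_rule,
    default_energy_params,
    pairwise_energy_score,
    rescale_hydropathy,
    score_proteome,
)


def _toy_energy_params(window=21, midpoint=-0.5, slope=0.25):
    """Two-letter toy model: A-A and G-G attract (-1), everything else 0."""
    m = np.zeros((20, 20))
    iA, iG = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("G")
    m[iA, iA] = m[iG, iG] = -1.0
    return EnergyModelParams(matrix=m, window=window, midpoint=midpoint,
                             slope=slope)


class TestChargeHydropathy:
    def test_homopolymer_isoleucine_is_ordered(self):
        track = charge_hydropathy_score(ProteinRecord("p", "I" * 80))
        np.testing.assert_allclose(track.scores, 2.785 * 1.0 - 1.151)
        assert not binarize(track, 0.0, "disordered_if_below").calls.any()

    def test_homopolymer_lysine_is_disordered(self):
        track = charge_hydropathy_score(ProteinRecord("p", "K" * 80))
        expected = 2.785 * ((-3.9 + 4.5) / 9) - 1.0 - 1.151
        np.testing.assert_allclose(track.scores, expected)
        assert binarize(track, 0.0, "disordered_if_below").calls.all()

    def test_single_residue_collapses_to_point_formula(self):
        track = charge_hydropathy_score(ProteinRecord("p", "D"))
        h = (KYTE_DOOLITTLE["D"] + 4.5) / 9
        np.testing.assert_allclose(track.scores, [2.785 * h - 1.0 - 1.151])

    @pytest.mark.parametrize("window", [0, 2, 10, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError, match="odd"):
            ChargeHydropathyParams(window=window)

    def test_x_residues_renormalized(self):
        # X must not dilute the window statistics
        a = charge_hydropathy_score(ProteinRecord("p", "IXXXI"),
                                    ChargeHydropathyParams(window=5))
        b = charge_hydropathy_score(ProteinRecord("p", "II"),
                                    ChargeHydropathyParams(window=5))
        np.testing.assert_allclose(a.scores[2], b.scores[0])

    def test_translation_invariance_on_homopolymer(self):
        params = ChargeHydropathyParams(window=11)
        track = charge_hydropathy_score(ProteinRecord("p", "L" * 40), params)
        interior = track.scores[5:-5]
        np.testing.assert_allclose(interior, interior[0])

    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_hydrophobic_substitution(self, seed):
        """Swapping a residue for a more hydrophobic, equally charged one
        never decreases any window score."""
        rng = np.random.default_rng(seed)
        neutral = [aa for aa in AMINO_ACIDS
                   if default_charge_rule()[aa] == 0]
        seq = list(random_protein(rng, 30))
        pos = int(rng.integers(0, 30))
        lo_aa, hi_aa = sorted(
            rng.choice(neutral, size=2, replace=False),
            key=lambda a: KYTE_DOOLITTLE[a])
        params = ChargeHydropathyParams(window=7)
        seq[pos] = lo_aa
        low = charge_hydropathy_score(
            ProteinRecord("p", "".join(seq)), params).scores
        seq[pos] = hi_aa
        high = charge_hydropathy_score(
            ProteinRecord("p", "".join(seq)), params).scores
        assert (high - low >= -1e-12).all()


class TestPairwiseEnergy:
    def test_homopolymer_toy_model(self):
        params = _toy_energy_params()
        track = pairwise_energy_score(ProteinRecord("p", "A" * 50), params)
        np.testing.assert_allclose(track.scores, 1.0 / (1.0 + np.e ** 2))
        assert not binarize(track, 0.5,
                            "disordered_if_at_or_above").calls.any()

    def test_alternating_hits_logistic_midpoint_tie(self):
        params = _toy_energy_params()
        track = pairwise_energy_score(
            ProteinRecord("p", "AG" * 25), params)
        mid = track.scores[12:-12]
        np.testing.assert_allclose(mid, 0.5)
        # probability-like tie resolves to disordered
        assert binarize(track, 0.5, "disordered_if_at_or_above").calls[25]

    def test_zero_matrix_gives_constant_scores(self):
        params = EnergyModelParams(matrix=np.zeros((20, 20)), window=5,
                                   midpoint=-0.3, slope=0.2)
        rng = np.random.default_rng(0)
        for seq in ("MKLVVG", random_protein(rng, 40)):
            track = pairwise_energy_score(ProteinRecord("p", seq), params)
            np.testing.assert_allclose(track.scores, track.scores[0])

    def test_window_one_rejected(self):
        with pytest.raises(ValueError, match="3"):
            _toy_energy_params(window=1)

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((20, 20))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            EnergyModelParams(matrix=m)

    def test_scores_lie_in_unit_interval(self, rng):
        params = default_energy_params()
        for _ in range(5):
            seq = random_protein(rng, int(rng.integers(1, 120)), x_prob=0.05)
            s = pairwise_energy_score(ProteinRecord("p", seq), params).scores
            assert ((s > 0) & (s < 1)).all()


class TestOracleEquivalence:
    """Both predictors against the direct-loop references (small scale;
    the full 1000-sequence sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_charge_hydropathy_matches_brute_force(self, window, rng):
        params = ChargeHydropathyParams(window=window)
        for _ in range(30):
            seq = random_protein(rng, int(rng.integers(1, 31)), x_prob=0.1)
            got = charge_hydropathy_score(
                ProteinRecord("p", seq), params).scores
            want = brute_charge_hydropathy(
                seq, params.hydropathy, params.charge, window=window)
            np.testing.assert_allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_pairwise_energy_matches_brute_force(self, window, rng):
        params = default_energy_params()
        params = EnergyModelParams(matrix=params.matrix, window=window,
                                   midpoint=params.midpoint,
                                   slope=params.slope)
        by_letter = {
            a: {b: params.matrix[i, j]
                for j, b in enumerate(AMINO_ACIDS)}
            for i, a in enumerate(AMINO_ACIDS)}
        for _ in range(30):
            seq = random_protein(rng, int(rng.integers(1, 31)), x_prob=0.1)
            got = pairwise_energy_score(
                ProteinRecord("p", seq), params).scores
            want = brute_pairwise_energy(seq, by_letter, window,
                                         params.midpoint, params.slope)
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestBinarize:
    def test_below_rule(self):
        from idrscan.seqio import ScoreTrack
        t = ScoreTrack("p", "x", np.array([-0.2, 0.3]))
        assert binarize(t, 0.0, "disordered_if_below").calls.tolist() == \
            [True, False]

    def test_tie_at_threshold(self):
        from idrscan.seqio import ScoreTrack
        t = ScoreTrack("p", "x", np.zeros(4))
        assert binarize(t, 0.0, "disordered_if_at_or_above").calls.all()
        assert not binarize(t, 0.0, "disordered_if_below").calls.any()

    def test_unknown_direction_rejected(self):
        from idrscan.seqio import ScoreTrack
        t = ScoreTrack("p", "x", np.zeros(2))
        with pytest.raises(ValueError, match="direction"):
            binarize(t, 0.0, "sideways")


def test_score_proteome_and_default_rules(toy_records):
    tracks = score_proteome(toy_records)
    assert {(t.protein_id, t.predictor) for t in tracks} == {
        ("p1", "charge_hydropathy"), ("p1", "pairwise_energy"),
        ("p2", "charge_hydropathy"), ("p2", "pairwise_energy")}
    calls = call_tracks(tracks)
    assert len(calls) == 4
    assert set(DEFAULT_CALL_RULES) == {"charge_hydropathy",
                                       "pairwise_energy"}


def test_recovery_on_contrasted_synthetic_proteome():
    """Residue-level balanced accuracy >= 0.9 for each predictor when
    ordered and disordered compositions are strongly contrasted."""
    from conftest import composition_vector
    from idrscan.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_proteins=30, length=(600, 600), regions_per_protein=(1, 1),
        region_length=(150, 200),
        ordered_composition=composition_vector(I=0.3, L=0.3, V=0.2, F=0.2),
        disordered_composition=composition_vector(E=0.35, K=0.35,
                                                  S=0.15, G=0.15),
        seed=42)
    records, truths = generate(spec)
    truth = {t.protein_id: t.labels for t in truths}
    calls = call_tracks(score_proteome(records))
    for pred in ("charge_hydropathy", "pairwise_energy"):
        tp = fp = tn = fn = 0
        for c in calls:
            if c.predictor != pred:
                continue
            t = truth[c.protein_id]
            tp += int((c.calls & t).sum())
            fp += int((c.calls & ~t).sum())
            tn += int((~c.calls & ~t).sum())
            fn += int((~c.calls & t).sum())
        balanced = (tp / (tp + fn) + tn / (tn + fp)) / 2
        assert balanced >= 0.9, f"{pred}: balanced accuracy {balanced:.3f}"
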