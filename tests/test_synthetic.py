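import numpy as np
import pytest
from scipy.stats import chisquare

import taphunter as th
from taphunter.errors import ValidationError
from taphunter.seqio import AMINO_ACIDS
from taphunter.synthetic import background_frequencies

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class TestDefaultProfile:
    def test_null_profile_is_background(self):
        prof = th.default_tap_profile(0.0)
        for slot in range(1, 10):
            assert np.allclose(prof.position_distribution(slot), prof.background)

    def test_proline_depleted_at_p1_p2(self):
        prof = th.default_tap_profile(1.5)
        for slot in (1, 2):
            assert prof.position_distribution(slot)[AA_INDEX["P"]] < 0.05

    def test_aromatics_enriched_at_anchor_slots(self):
        prof = th.default_tap_profile(1.5)
        for slot in (1, 3, 7, 9):
            dist = prof.position_distribution(slot)
            for aa in "FWY":
                assert dist[AA_INDEX[aa]] > 0.05

    def test_distributions_normalized(self):
        prof = th.default_tap_profile(2.0)
        for slot in range(1, 10):
            assert prof.position_distribution(slot).sum() == pytest.approx(1, abs=1e-12)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValidationError):
            th.default_tap_profile(-0.5)

    def test_natural_background_available(self):
        bg = background_frequencies("natural")
        assert bg.sum() == pytest.approx(1.0)
        assert bg[AA_INDEX["L"]] > bg[AA_INDEX["W"]]


class TestGenerate:
    def test_count_contract_and_uniqueness(self):
        ds = th.generate(th.default_tap_profile(2.0), 276, 94, seed=7)
        pset = ds.peptides
        assert len(pset) == 370
        assert pset.n_pos == 276 and pset.n_neg == 94
        assert len(set(pset.sequences)) == 370
        assert all(len(p) == 9 for p, _ in pset)

    def test_bit_reproducible(self):
        prof = th.default_tap_profile(1.0)
        a = th.generate(prof, 50, 20, seed=3).peptides
        b = th.generate(prof, 50, 20, seed=3).peptides
        assert a.sequences == b.sequences and a.labels == b.labels

    def test_null_classes_indistinguishable(self):
        ds = th.generate(th.default_tap_profile(0.0), 2500, 2500, seed=5)
        pos_p1 = np.zeros(20)
        neg_p1 = np.zeros(20)
        for pep, y in ds.peptides:
            (pos_p1 if y == 1 else neg_p1)[AA_INDEX[pep.sequence[0]]] += 1
        pos_p1 /= pos_p1.sum()
        neg_p1 /= neg_p1.sum()
        assert np.max(np.abs(pos_p1 - neg_p1)) < 0.03

    def test_capacity_error(self):
        prof = th.default_tap_profile(0.0, length_distribution={4: 1.0})
        with pytest.raises(ValidationError):
            th.generate(prof, 200_000, 1, seed=0)

    def test_variable_lengths(self):
        prof = th.default_tap_profile(
            1.0, length_distribution={9: 0.5, 10: 0.25, 11: 0.25}
        )
        ds = th.generate(prof, 200, 100, seed=2)
        lengths = {len(p) for p, _ in ds.peptides}
        assert lengths == {9, 10, 11}

    def test_binder_frequencies_match_profile(self):
        """Chi-square goodness of fit of generated binder residues at the
        anchor slots against the profile's distributions (alpha = 0.001)."""
        prof = th.default_tap_profile(1.0)
        ds = th.generate(prof, 10_000, 1, seed=13)
        for slot in (1, 2, 3, 9):
            counts = np.zeros(20)
            for pep, y in ds.peptides:
                if y == 1:
                    counts[AA_INDEX[pep.sequence[slot - 1 if slot != 9 else 8]]] += 1
            expected = prof.position_distribution(slot) * counts.sum()
            _, p = chisquare(counts, expected)
            assert p > 0.001


class TestImplantProtein:
    def test_construction_contract(self):
        prof = th.default_tap_profile(2.0)
        protein, starts = th.generate_protein_with_implants(prof, 100, 2, 9, seed=1)
        assert len(protein) == 100
        assert len(starts) == 2
        for a, b in zip(starts, starts[1:]):
            assert b - a >= 9  # non-overlapping

    def test_zero_implants_pure_background(self):
        prof = th.default_tap_profile(2.0)
        protein, starts = th.generate_protein_with_implants(prof, 60, 0, 9, seed=1)
        assert starts == [] and len(protein) == 60

    def test_infeasible_packing(self):
        prof = th.default_tap_profile(2.0)
        with pytest.raises(ValidationError):
            th.generate_protein_with_implants(prof, 20, 3, 9, seed=1)

    def test_scan_ranks_implants_above_background(self, strong_dataset, anchor_config):
        """End to end: a trained model scores implanted windows above the
        median background window of the same protein."""
        prof = th.default_tap_profile(2.0)
        X, y = th.encode_set(strong_dataset, anchor_config)
        clf = th.TapBinderClassifier().fit(X, y)
        enc = th.PeptideEncoder(anchor_config.positions).fit([])
        protein, starts = th.generate_protein_with_implants(prof, 300, 3, 9, seed=21)
        windows = th.cleave_protein(protein, 9)
        scores = clf.decision_function(enc.transform([p.sequence for p, _ in windows]))
        by_start = {s: sc for (_, s), sc in zip(windows, scores)}
        background_scores = [sc for (_, s), sc in zip(windows, scores) if s not in starts]
        med = np.median(background_scores)
        assert all(by_start[s] > med for s in starts)


class TestPipelineCalibration:
    def test_auc_monotone_in_effect_size(self, anchor_config):
        """Seed-averaged CV AROC is non-decreasing in the motif strength."""
        means = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            aucs = [
                th.cross_validate(
                    th.generate(th.default_tap_profile(effect), 138, 47, seed=s).peptides,
                    anchor_config, k=5, seed=s,
                ).mean_auc
                for s in range(3)
            ]
            means.append(np.mean(aucs))
        assert all(a <= b + 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]
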