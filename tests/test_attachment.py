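"""Attachment classification, eligibility filtering and transition scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nichedyn as nd
from nichedyn.attachment import (StatusSequence, per_cell_attached_fraction,
                                 sequences_from_scene)
from nichedyn.simulate import TipSphere


def transitions_oracle(codes):
    """Independent pairwise scan: adjacent unequal pairs within {1,2,3}."""
    n = 0
    for a, b in zip(codes[:-1], codes[1:]):
        if a in (1, 2, 3) and b in (1, 2, 3) and a != b:
            n += 1
    return n


def seq(codes, cell_id=0, first=0):
    codes = np.asarray(codes)
    return StatusSequence(cell_id, np.arange(first, first + len(codes)), codes)


class TestClassify:
    def tip(self):
        return {f: TipSphere(np.array([0.0, 0.0, 0.0]), 10.0)
                for f in range(10)}

    def test_touching_cell_is_attached_every_frame(self):
        # membrane of a 4 µm cell at centre distance 14 touches the surface
        pos = np.tile([14.0, 0.0, 0.0], (5, 1))
        t = nd.CellTrack(cell_id=1, frames=np.arange(5), positions=pos)
        out = nd.classify_status(t, self.tip(), attach_distance=1.0,
                                 cell_radius=4.0)
        assert np.all(out.codes == 1)

    def test_distant_cell_is_unattached(self):
        pos = np.tile([30.0, 0.0, 0.0], (5, 1))
        t = nd.CellTrack(cell_id=1, frames=np.arange(5), positions=pos)
        out = nd.classify_status(t, self.tip(), attach_distance=1.0,
                                 cell_radius=4.0)
        assert np.all(out.codes == 2)

    def test_event_annotations_override(self):
        pos = np.tile([14.0, 0.0, 0.0], (6, 1))
        t = nd.CellTrack(cell_id=1, frames=np.arange(6), positions=pos)
        out = nd.classify_status(t, self.tip(), division_frames=[2],
                                 censor_frames=[4])
        np.testing.assert_array_equal(out.codes, [1, 1, 3, 1, 5, 5])

    def test_missing_surface_censors(self):
        pos = np.tile([14.0, 0.0, 0.0], (5, 1))
        t = nd.CellTrack(cell_id=1, frames=np.arange(5), positions=pos)
        tips = {f: TipSphere(np.zeros(3), 10.0) for f in range(3)}
        out = nd.classify_status(t, tips)
        np.testing.assert_array_equal(out.codes, [1, 1, 1, 5, 5])

    def test_negative_threshold_rejected(self):
        t = nd.CellTrack(cell_id=1, frames=[0, 1],
                         positions=[[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="attach_distance"):
            nd.classify_status(t, self.tip(), attach_distance=-1.0)

    def test_noiseless_scene_recovered_exactly(self, noiseless_scene):
        """At zero membrane jitter the geometric classifier reproduces the
        generator's true status at every analysed cell-frame."""
        scene = noiseless_scene
        tips = {f: scene.tip(f) for f in range(scene.n_frames)}
        n_match = n_total = 0
        for c in scene.cells:
            t = nd.CellTrack(cell_id=c.cell_id, frames=c.frames,
                             positions=c.observed_positions)
            division = np.flatnonzero(c.status == 3).tolist()
            out = nd.classify_status(t, tips, attach_distance=1.0,
                                     cell_radius=scene.params.cell_radius,
                                     division_frames=division)
            truth = c.status[c.frames]
            n_match += int(np.sum(out.codes == truth))
            n_total += len(truth)
        assert n_total > 0
        assert n_match / n_total >= 0.99
        assert n_match == n_total  # exact at zero noise

    def test_classify_then_count_recovers_true_counts(self, noiseless_scene):
        scene = noiseless_scene
        tips = {f: scene.tip(f) for f in range(scene.n_frames)}
        for c in scene.cells:
            t = nd.CellTrack(cell_id=c.cell_id, frames=c.frames,
                             positions=c.observed_positions)
            division = np.flatnonzero(c.status == 3).tolist()
            out = nd.classify_status(t, tips,
                                     cell_radius=scene.params.cell_radius,
                                     division_frames=division)
            assert nd.count_transitions(out.codes) == \
                nd.count_transitions(c.status[c.frames])


class TestEligibility:
    def test_clean_sequence_kept(self):
        kept, dropped = nd.filter_eligible([seq([1, 1, 2, 1])])
        assert len(kept) == 1 and dropped == 0

    def test_censored_sequence_dropped(self):
        kept, dropped = nd.filter_eligible([seq([1, 5, 5, 5])])
        assert len(kept) == 0 and dropped == 1

    def test_mixed_set_counts(self):
        seqs = [seq([1, 2, 1], cell_id=i) for i in range(7)]
        seqs += [seq([1, 4, 4], cell_id=7), seq([2, 5, 5], cell_id=8),
                 seq([1, 1, 5], cell_id=9)]
        kept, dropped = nd.filter_eligible(seqs)
        assert len(kept) == 7 and dropped == 3

    def test_absorbing_invariant_enforced(self):
        with pytest.raises(ValueError, match="absorbing"):
            seq([1, 5, 1])


class TestTransitionCount:
    @pytest.mark.parametrize("codes,expected", [
        ([1, 1, 1, 1], 0),
        ([1, 2, 1, 2, 1], 4),
        ([2, 1, 1, 3, 1, 1, 2], 4),
        ([1, 3, 1], 2),
        ([1, 2, 4, 4], 1),
        ([5, 5, 5], 0),
        ([1], 0),
    ])
    def test_worked_examples(self, codes, expected):
        assert nd.count_transitions(codes) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nd.count_transitions([])

    def test_exhaustive_oracle_active_codes_up_to_length_six(self):
        """Matches the brute-force pairwise scan on every sequence of
        length <= 6 over the active codes {1, 2, 3}."""
        for n in range(1, 7):
            for codes in itertools.product((1, 2, 3), repeat=n):
                assert nd.count_transitions(codes) == transitions_oracle(codes)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=1,
                    max_size=12))
    def test_matches_oracle_on_arbitrary_code_strings(self, codes):
        assert nd.count_transitions(codes) == transitions_oracle(codes)

    def test_inserting_a_switch_raises_count_by_two_or_one(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            codes = rng.integers(1, 4, size=10).tolist()
            base = nd.count_transitions(codes)
            # there-and-back insertion in the interior of a constant run
            i = int(rng.integers(1, 9))
            flank = codes[i - 1]
            other = 1 if flank != 1 else 2
            inserted = codes[:i] + [other, flank] + codes[i:]
            if codes[i] == flank:  # insertion splits a constant pair
                assert nd.count_transitions(inserted) == base + 2
            # terminal switch appends exactly one change
            tail = codes + [1 if codes[-1] != 1 else 2]
            assert nd.count_transitions(tail) == base + 1


class TestAttachmentFraction:
    def test_all_attached(self):
        seqs = [seq([1, 1, 1], cell_id=i) for i in range(5)]
        assert nd.attachment_fraction(seqs, 1) == 1.0

    def test_three_of_four(self):
        seqs = [seq([1]), seq([1], 1), seq([1], 2), seq([2], 3)]
        assert nd.attachment_fraction(seqs, 0) == 0.75

    def test_no_eligible_cells_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            nd.attachment_fraction([seq([3])], 0)

    def test_stationary_fraction_matches_markov_law(self):
        """A large generated cohort at stationarity has attachment fraction
        within 3 SE of p_attach / (p_attach + p_detach)."""
        p_detach, p_attach = 0.05, 0.2
        pi = p_attach / (p_attach + p_detach)
        params = nd.SceneParameters(
            n_cells=60, n_frames=98, p_detach=p_detach, p_attach=p_attach,
            p_divide=0.0, p_exit=0.0, initial_attached_fraction=pi, seed=21)
        scene = nd.generate_scene(params)
        seqs = sequences_from_scene(scene)
        fracs = [nd.attachment_fraction(seqs, f) for f in range(60, 98)]
        se = np.sqrt(pi * (1 - pi) / params.n_cells)
        assert abs(np.mean(fracs) - pi) < 3 * se

    def test_per_cell_fraction_ignores_division_frames(self):
        s = seq([1, 3, 1, 2])
        assert per_cell_attached_fraction(s) == pytest.approx(2 / 3)


class TestGroupSummary:
    def test_constant_group_mean_zero_sem_zero(self):
        seqs = [seq([1] * 10, cell_id=i) for i in range(4)]
        out = nd.group_transition_summary({"control": seqs})
        row = out.iloc[0]
        assert row["mean_transitions"] == 0.0 and row["sem"] == 0.0

    def test_fold_difference_arithmetic(self):
        a = [seq([1] * 5), seq([1] * 5, 1), seq([1, 1, 1, 1, 2], 2)]
        b = [seq([1, 2, 1, 2, 1], cell_id=i) for i in range(3)]
        out = nd.group_transition_summary({"a": a, "b": b})
        means = out.set_index("group")["mean_transitions"]
        assert means["b"] / means["a"] == pytest.approx(12.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nd.group_transition_summary({"a": []})

    def test_initial_state_stratification(self):
        s_att = seq([1, 2, 1], cell_id=0, first=10)
        s_det = seq([2, 1, 2], cell_id=1, first=10)
        out = nd.group_transition_summary({"g": [s_att, s_det]},
                                          initial_state_frame=10)
        strata = set(out["initial_state"])
        assert {"attached", "unattached", "all"} <= strata

    def test_presets_reproduce_fourfold_switching_regime(self):
        """Chain-level control-like (p_detach 0.005) vs mutant-like
        (p_detach 0.05, p_attach 0.2) cohorts of 30 cells x 88 analysed
        frames: the mutant mean transition count exceeds the control mean
        >= 4-fold in >= 95% of 100 seeded replicates."""
        rng = np.random.default_rng(77)

        def cohort_mean(p_detach, initial_attached):
            counts = []
            for i in range(30):
                init = 1 if i < round(initial_attached * 30) else 2
                codes = nd.simulate_status_chain(p_detach, 0.2, 0.001, 0.001,
                                                 98, init, rng=rng)
                codes = codes[10:98]
                if np.any(np.isin(codes, (4, 5))):
                    continue
                counts.append(nd.count_transitions(codes))
            return np.mean(counts)

        hits = 0
        for _ in range(100):
            c = cohort_mean(0.005, 1.0)
            m = cohort_mean(0.05, 0.5)
            hits += (c == 0) or (m / c >= 4.0)
        assert hits >= 95
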