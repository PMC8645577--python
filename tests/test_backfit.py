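"""Backfitting, label smoothing and the Duration/Frequency/Coverage table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import eegmicrostates as em
from eegmicrostates.backfit import UNASSIGNED, run_length_encode


def _epochset_from_labels(labels, maps, srate=500.0, amplitude=1.0):
    """Epochs whose topography at t is exactly the labeled template."""
    labels = np.atleast_2d(labels)
    e, l = labels.shape
    epochs = maps.maps[labels.reshape(-1)].reshape(e, l, maps.n_channels)
    epochs = np.transpose(epochs, (0, 2, 1)) * amplitude
    return em.EpochSet("s1", "control", epochs, srate,
                       epoch_seconds=l / srate, reference="average")


def _rle_list(seq):
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((start, i, seq[start]))
            start = i
    return runs


def _brute_force_smooth(labels, corr, min_len):
    """Independent reference smoothing: literal, one shortest run at a time."""
    seq = list(labels)
    max_steps = 10 * max(1, len(_rle_list(seq)))
    for _ in range(max_steps):
        runs = _rle_list(seq)
        short = [
            (e - s, ri)
            for ri, (s, e, v) in enumerate(runs)
            if (e - s) < min_len and v != UNASSIGNED
        ]
        if not short:
            break
        _, ri = min(short)  # shortest first, leftmost on ties
        s, e, _v = runs[ri]
        left = runs[ri - 1][2] if ri > 0 else None
        right = runs[ri + 1][2] if ri < len(runs) - 1 else None
        if left is None and right is None:
            break
        for t in range(s, e):
            if left is None:
                seq[t] = right
            elif right is None:
                seq[t] = left
            else:
                cl = corr[t, left] if left != UNASSIGNED else -np.inf
                cr = corr[t, right] if right != UNASSIGNED else -np.inf
                seq[t] = left if cl >= cr else right
    # terminal cleanup: contiguous two-segment split of each short-run zone
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((start, i, seq[start]))
            start = i
    if len(runs) >= 3:
        member = [
            0 < ri < len(runs) - 1
            and (runs[ri][1] - runs[ri][0]) < min_len
            and runs[ri][2] != UNASSIGNED
            for ri in range(len(runs))
        ]
        ri = 0
        while ri < len(runs):
            if not member[ri]:
                ri += 1
                continue
            rj = ri
            while rj + 1 < len(runs) and member[rj + 1]:
                rj += 1
            s, e = runs[ri][0], runs[rj][1]
            left, right = runs[ri - 1][2], runs[rj + 1][2]
            if left == right:
                for t in range(s, e):
                    seq[t] = left
            elif not (left == UNASSIGNED and right == UNASSIGNED):
                best_j, best_score = 0, -np.inf
                for j in range(e - s + 1):
                    score = sum(
                        (corr[t, left] if left != UNASSIGNED else -np.inf)
                        for t in range(s, s + j)
                    ) + sum(
                        (corr[t, right] if right != UNASSIGNED else -np.inf)
                        for t in range(s + j, e)
                    )
                    if score > best_score:
                        best_score, best_j = score, j
                for t in range(s, s + best_j):
                    seq[t] = left
                for t in range(s + best_j, e):
                    seq[t] = right
            ri = rj + 1
    return np.array(seq)


class TestBackfit:
    def test_pure_template_epoch_fully_labeled(self, templates64):
        labels = np.full((1, 50), 1)  # class B everywhere
        es = _epochset_from_labels(labels, templates64)
        ls = em.backfit(es, templates64)
        np.testing.assert_array_equal(ls.labels, 1)
        np.testing.assert_allclose(ls.correlation_trace, 1.0, atol=1e-10)

    def test_low_correlation_goes_unassigned(self, rng):
        maps = em.MicrostateMaps(
            np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]]), ["A", "B"]
        )
        # sample orthogonal to both templates
        epochs = np.array([[1.0, 1.0, -1.0, -1.0]]).T[None, :, :]
        es = em.EpochSet("s", "control", epochs, 500.0, epoch_seconds=1 / 500,
                         reference="average")
        ls = em.backfit(es, maps, min_corr=0.5)
        assert ls.labels[0, 0] == UNASSIGNED

    def test_channel_mismatch_rejected(self, templates64, rng):
        epochs = rng.normal(size=(1, 32, 10))
        es = em.EpochSet("s", "control", epochs, 500.0, epoch_seconds=10 / 500)
        with pytest.raises(em.FormatError):
            em.backfit(es, templates64)

    def test_planted_sequence_recovered_through_preprocessing(self, small_cohort):
        """Samplewise agreement with ground truth >= 90% at default noise."""
        rec = small_cohort.recordings[0]
        truth = small_cohort.ground_truth
        with pytest.warns(UserWarning):
            es = em.preprocess_recording(rec, min_epochs=30)
        ls = em.smooth_labels(em.backfit(es, truth.templates), 20.0)
        true_labels = truth.labels[rec.subject_id][:, ::2]  # 1000 -> 500 Hz
        assert (ls.labels == true_labels).mean() >= 0.90


class TestSmoothing:
    def _ls(self, labels, corr, srate=500.0):
        labels = np.atleast_2d(np.asarray(labels))
        corr = np.asarray(corr)[None, ...] if corr.ndim == 2 else corr
        return em.LabelSequence(labels=labels, srate=srate, correlations=corr,
                                class_labels=["A", "B", "C", "D"])

    def test_single_sample_island_absorbed(self):
        labels = [0] * 4 + [1] + [0] * 4
        corr = np.full((9, 4), 0.5)
        ls = self._ls(labels, corr)
        out = em.smooth_labels(ls, min_duration_ms=2 / 500 * 1000)  # 2 samples
        np.testing.assert_array_equal(out.labels[0], 0)

    def test_idempotent_when_all_runs_long(self):
        labels = [0] * 20 + [1] * 20 + [2] * 10
        corr = np.full((50, 4), 0.5)
        ls = self._ls(labels, corr)
        out = em.smooth_labels(ls, 20.0)  # 10 samples at 500 Hz
        np.testing.assert_array_equal(out.labels, ls.labels)

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 51))
            labels = rng.integers(0, 4, size=n)
            corr = rng.uniform(0, 1, size=(n, 4))
            ls = self._ls(labels, corr)
            min_ms = float(rng.choice([4, 8, 12])) / 500 * 1000
            got = em.smooth_labels(ls, min_ms).labels[0]
            want = _brute_force_smooth(labels, corr,
                                       int(round(min_ms * 500 / 1000)))
            np.testing.assert_array_equal(got, want)

    def test_no_short_interior_runs_after_smoothing(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 4, size=(2, 200))
            corr = r.uniform(0, 1, size=(2, 200, 4))
            ls = self._ls(labels, corr)
            out = em.smooth_labels(ls, 20.0)  # 10 samples
            for ep in out.labels:
                values, lengths = run_length_encode(ep)
                # interior runs obey the floor; epoch-edge runs may not
                if len(lengths) > 2:
                    assert lengths[1:-1].min() >= 10

    def test_smoothing_preserves_long_runs_on_pipeline_output(self, small_cohort):
        rec = small_cohort.recordings[0]
        with pytest.warns(UserWarning):
            es = em.preprocess_recording(rec, min_epochs=30)
        ls = em.backfit(es, small_cohort.ground_truth.templates)
        out = em.smooth_labels(ls, 20.0)
        for ep in out.labels:
            values, lengths = run_length_encode(ep)
            if len(lengths) > 2:
                assert lengths[1:-1].min() >= 10


class TestParameters:
    def test_hand_counted_example(self):
        # one 40-sample epoch at 500 Hz: A x10, B x10, A x20
        labels = np.array([[0] * 10 + [1] * 10 + [0] * 20])
        table = em.parameters_from_labels(labels, 500.0, 2)
        a, b = table.iloc[0], table.iloc[1]
        assert a.duration_ms == pytest.approx(30.0)  # runs 10, 20 -> mean 15
        assert a.frequency_per_s == pytest.approx(25.0)  # 2 runs / 0.08 s
        assert a.coverage_fraction == pytest.approx(0.75)
        assert b.duration_ms == pytest.approx(20.0)
        # identity: coverage = frequency x duration
        assert a.coverage_fraction == pytest.approx(
            a.frequency_per_s * a.duration_ms / 1000.0
        )

    def test_single_class_everywhere(self):
        labels = np.zeros((3, 100), dtype=int)
        table = em.parameters_from_labels(labels, 500.0, 2)
        assert table.iloc[0].coverage_fraction == pytest.approx(1.0)
        assert table.iloc[0].frequency_per_s == pytest.approx(3 / (300 / 500))
        assert np.isnan(table.iloc[1].duration_ms)
        assert table.iloc[1].frequency_per_s == 0.0

    def test_matches_bruteforce_rle(self, rng):
        labels = rng.integers(-1, 4, size=(5, 80))
        got = em.parameters_from_labels(labels, 500.0, 4)
        # independent oracle: literal python run-length counting per epoch
        runs = {k: [] for k in range(4)}
        for ep in labels:
            cur, n = None, 0
            for v in list(ep) + [None]:
                if v == cur:
                    n += 1
                else:
                    if cur is not None and cur >= 0:
                        runs[cur].append(n)
                    cur, n = v, 1
        total_s = labels.size / 500.0
        for k in range(4):
            row = got.iloc[k]
            if runs[k]:
                assert row.duration_ms == pytest.approx(
                    np.mean(runs[k]) / 500 * 1000
                )
            else:
                assert np.isnan(row.duration_ms)
            assert row.frequency_per_s == pytest.approx(len(runs[k]) / total_s)
            assert row.coverage_fraction == pytest.approx(
                sum(runs[k]) / labels.size
            )

    def test_coverage_identity_and_sum_with_unassigned(self, rng):
        labels = rng.integers(-1, 4, size=(4, 200))
        table = em.parameters_from_labels(labels, 500.0, 4)
        cov = table.coverage_fraction.to_numpy()
        freq = table.frequency_per_s.to_numpy()
        dur = table.duration_ms.to_numpy()
        occurring = freq > 0
        np.testing.assert_allclose(
            cov[occurring], (freq * dur / 1000.0)[occurring], rtol=1e-12
        )
        unassigned = (labels == UNASSIGNED).mean()
        assert cov.sum() + unassigned == pytest.approx(1.0, abs=1e-12)


class TestCohortTable:
    def _subject_table(self, sid, group, rng):
        labels = rng.integers(0, 4, size=(2, 100))
        ls = em.LabelSequence(
            labels=labels, srate=500.0,
            correlations=rng.uniform(size=(2, 100, 4)),
            class_labels=["A", "B", "C", "D"],
        )
        return em.compute_parameters(ls, sid, group, gev=0.8)

    def test_single_subject_groups_have_missing_sd(self, rng):
        tables = [
            self._subject_table("s1", "seizure", rng),
            self._subject_table("s2", "control", rng),
        ]
        summary = em.summarize_cohort(em.build_cohort_table(tables))
        assert summary["duration_ms_sd"].isna().all()
        assert summary["duration_ms_mean"].notna().all()

    def test_identical_subjects_have_zero_sd(self, templates64):
        labels = np.array([[0] * 30 + [1] * 30 + [2] * 40])
        tables = []
        for sid in ["s1", "s2", "s3"]:
            ls = em.LabelSequence(
                labels=labels, srate=500.0,
                correlations=np.full((1, 100, 4), 0.9),
                class_labels=["A", "B", "C", "D"],
            )
            tables.append(em.compute_parameters(ls, sid, "control"))
        summary = em.summarize_cohort(em.build_cohort_table(tables))
        np.testing.assert_allclose(summary["coverage_pct_sd"], 0.0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(em.ParameterError):
            em.build_cohort_table([])
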