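import os

import numpy as np
import pytest

from clops.signal_data import (
    DEFAULT_CLASS_PALETTE,
    ClassMorphology,
    CorruptStreamError,
    SyntheticConfig,
    make_stream,
    read_stream,
    read_wfdb_record,
    synthesize_segment,
    time_il_prevalences,
    write_stream,
)


class TestSynthesizeSegment:
    def test_zero_amplitudes_zero_noise_gives_zero_trace(self):
        params = ClassMorphology(60, 0.0, 0.08, 0.0, 0.0, 0.0,
                                 r_amp=0.0, q_amp=0.0, s_amp=0.0)
        sig = synthesize_segment(params, 0.0, 500, 100.0, seed=3)
        np.testing.assert_array_equal(sig, np.zeros(500))

    def test_deterministic_under_seed(self):
        params = DEFAULT_CLASS_PALETTE[0]
        a = synthesize_segment(params, 0.1, 400, 100.0, seed=7)
        b = synthesize_segment(params, 0.1, 400, 100.0, seed=7)
        assert np.array_equal(a, b)
        c = synthesize_segment(params, 0.1, 400, 100.0, seed=8)
        assert not np.array_equal(a, c)

    def test_beat_onsets_at_60bpm_metronomic(self):
        params = ClassMorphology(60, 0.0, 0.08, 0.0, 0.15, 0.3)
        _, onsets = synthesize_segment(
            params, 0.0, 2500, 250.0, seed=0, return_onsets=True
        )
        assert len(onsets) == 10
        assert np.all(np.diff(onsets) == 250)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rate_bpm=-60), dict(rate_bpm=0), dict(rr_cv=1.5),
            dict(qrs_width_s=0),
        ],
    )
    def test_invalid_morphology_rejected(self, kwargs):
        base = dict(rate_bpm=60, rr_cv=0.05, qrs_width_s=0.08,
                    st_offset=0.0, p_amp=0.1, t_amp=0.3)
        base.update(kwargs)
        with pytest.raises(ValueError):
            synthesize_segment(ClassMorphology(**base), 0.1, 100, 50.0, 0)

    def test_nonpositive_length_or_rate_rejected(self):
        with pytest.raises(ValueError):
            synthesize_segment(DEFAULT_CLASS_PALETTE[0], 0.1, 0, 50.0, 0)
        with pytest.raises(ValueError):
            synthesize_segment(DEFAULT_CLASS_PALETTE[0], 0.1, 100, -1.0, 0)


class TestScenarios:
    def test_class_il_pairs_cover_twelve_classes(self):
        cfg = SyntheticConfig(n_classes=12, L=200, fs=50.0, n_train=2, n_val=2,
                              n_test=2, segments_per_patient=1)
        stream = make_stream("class_il", cfg)
        assert stream.n_tasks == 6
        assert stream.head_policy == "per_task"
        pairs = [sorted(t.class_set) for t in stream.tasks]
        assert pairs == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9], [10, 11]]

    def test_class_il_odd_classes_rejected(self):
        cfg = SyntheticConfig(n_classes=5, L=200, fs=50.0, n_train=2, n_val=2,
                              n_test=2)
        with pytest.raises(ValueError):
            make_stream("class_il", cfg)

    def test_time_il_prevalence_recovered(self):
        cfg = SyntheticConfig(n_classes=4, L=200, fs=50.0, n_train=40, n_val=8,
                              n_test=8)
        stream = make_stream("time_il", cfg)
        assert stream.n_tasks == 3
        assert stream.head_policy == "shared"
        prev = time_il_prevalences(4)
        for term, task in enumerate(stream.tasks):
            train = task.split_segments("train")
            freq = np.bincount([s.label for s in train], minlength=4) / len(train)
            # largest-remainder allocation: within one count of exact
            assert np.all(np.abs(freq - prev[term]) <= 1.5 / len(train))

    def test_domain_il_is_projections_of_one_latent(self):
        cfg = SyntheticConfig(n_classes=2, L=300, fs=50.0, n_train=3, n_val=2,
                              n_test=2, segments_per_patient=1)
        stream = make_stream("domain_il", cfg)
        assert stream.n_tasks == 12
        by_source = {}
        for task in stream.tasks:
            for seg in task.segments:
                by_source.setdefault(seg.source_id, []).append(seg.signal)
        # all 12 lead signals of one source are (noisy) scalar multiples of
        # one latent trace: pairwise |correlation| is high
        sigs = np.stack(next(iter(by_source.values())))
        assert sigs.shape[0] == 12
        cc = np.corrcoef(sigs)
        off_diag = np.abs(cc[np.triu_indices(12, 1)])
        assert np.median(off_diag) > 0.8

    def test_institute_il_disjoint_vocabularies_common_length(self):
        cfg = SyntheticConfig(n_classes=6, L=300, fs=50.0, n_train=2, n_val=2,
                              n_test=2, segments_per_patient=1)
        stream = make_stream("institute_il", cfg)
        assert stream.n_tasks >= 3
        sets = [t.class_set for t in stream.tasks]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])
        for t in stream.tasks:
            for seg in t.segments:
                assert len(seg.signal) == cfg.L

    def test_patient_disjoint_splits(self, tiny_stream):
        for task in tiny_stream.tasks:
            by_split = {}
            for seg in task.segments:
                by_split.setdefault(seg.split, set()).add(seg.patient_id)
            splits = list(by_split.values())
            for i in range(len(splits)):
                for j in range(i + 1, len(splits)):
                    assert not (splits[i] & splits[j])


class TestStreamIO:
    def test_round_trip_bytes(self, tiny_stream, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_stream(tiny_stream, str(d1))
        recovered = read_stream(str(d1))
        write_stream(recovered, str(d2))
        for name in ("manifest.csv", "signals.npz"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        for t0, t1 in zip(tiny_stream.tasks, recovered.tasks):
            assert t0.class_set == t1.class_set
            for a, b in zip(
                sorted(t0.segments, key=lambda s: s.instance_id),
                sorted(t1.segments, key=lambda s: s.instance_id),
            ):
                assert np.array_equal(a.signal, b.signal)
                assert (a.label, a.split, a.fs) == (b.label, b.split, b.fs)

    def test_manifest_signal_mismatch_raises(self, tiny_stream, tmp_path):
        d = tmp_path / "s"
        write_stream(tiny_stream, str(d))
        with np.load(d / "signals.npz") as z:
            signals = z["signals"]
        np.savez(d / "signals.npz", signals=signals[:-1])
        with pytest.raises(CorruptStreamError):
            read_stream(str(d))


class TestWFDBAdapter:
    def test_reads_fixture_written_independently(self, tmp_path):
        # fixture written here with plain struct/bytes, independent of the reader
        fs, n_samp, gain, baseline = 125.0, 50, 100.0, 12
        rng = np.random.default_rng(5)
        phys = np.round(rng.standard_normal((n_samp, 2)), 2)
        digital = np.asarray(phys * gain + baseline, dtype="<i2")
        (tmp_path / "rec01.hea").write_text(
            f"rec01 2 {fs:g} {n_samp}\n"
            f"rec01.dat 16 {gain:g}({baseline}) 0 0 0 0 0 I\n"
            f"rec01.dat 16 {gain:g}({baseline}) 0 0 0 0 0 II\n"
        )
        (tmp_path / "rec01.dat").write_bytes(digital.tobytes())
        segs = read_wfdb_record(str(tmp_path / "rec01"))
        assert len(segs) == 2
        for ch in range(2):
            assert segs[ch].fs == fs
            assert len(segs[ch].signal) == n_samp
            expect = (digital[:, ch].astype(float) - baseline) / gain
            np.testing.assert_allclose(segs[ch].signal, expect)

    def test_unsupported_format_rejected(self, tmp_path):
        (tmp_path / "r.hea").write_text("r 1 100 10\nr.dat 212 200 0 0\n")
        (tmp_path / "r.dat").write_bytes(b"\x00" * 20)
        with pytest.raises(ValueError):
            read_wfdb_record(str(tmp_path / "r"))
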