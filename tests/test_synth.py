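import numpy as np
import pytest

from eegperm.connectivity import msc_matrix
from eegperm.preprocess import segment
from eegperm.spectral import BAND_NAMES, band_power_table
from eegperm.synth import (
    Artifact,
    SynthConfig,
    generate_recording,
    generate_study,
    inject_artifacts,
)

LAB8 = tuple(f"ch{i}" for i in range(8))


def _cfg(**kw):
    base = dict(n_channels=8, fs=256.0, duration=20.0, labels=LAB8)
    base.update(kw)
    return SynthConfig(**base)


class TestGenerateRecording:
    def test_seed_determinism_bit_identical(self):
        cfg = _cfg()
        a = generate_recording(cfg, seed=11)
        b = generate_recording(cfg, seed=11)
        assert (a.data == b.data).all()
        c = generate_recording(cfg, seed=12)
        assert not (a.data == c.data).all()

    def test_single_band_signal_is_nearly_pure(self):
        weights = {b: 0.0 for b in BAND_NAMES}
        weights["alpha1"] = 1.0
        rec = generate_recording(_cfg(band_weights=weights, noise_floor=0.5), seed=2)
        table = band_power_table(segment(rec, 5.0))
        assert table.mean(axis=(0, 1))[BAND_NAMES.index("alpha1")] >= 0.9

    def test_zero_gain_gives_incoherent_channels(self):
        rec = generate_recording(_cfg(shared_source_gain=0.0, duration=30.0), seed=3)
        freqs, m = msc_matrix(rec.data, rec.fs, seg_len=1.0, overlap=0.5)
        off = ~np.eye(rec.n_channels, dtype=bool)
        for lo, hi in ((0.5, 4), (8, 11), (25, 35)):
            band = (freqs >= lo) & (freqs < hi)
            assert m[:, :, band].mean(axis=2)[off].mean() <= 0.1

    def test_coherence_monotone_in_shared_gain(self):
        means = []
        for g in (0.1, 0.5, 0.9):
            rec = generate_recording(_cfg(shared_source_gain=g, duration=30.0), seed=4)
            freqs, m = msc_matrix(rec.data, rec.fs)
            off = ~np.eye(rec.n_channels, dtype=bool)
            band = (freqs >= 0.5) & (freqs < 40.0)
            means.append(float(m[:, :, band].mean(axis=2)[off].mean()))
        assert means[0] < means[1] < means[2]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            generate_recording(_cfg(band_weights={"delta": -0.1}), seed=0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            generate_recording(_cfg(shared_source_gain=1.5), seed=0)
        with pytest.raises(ValueError, match="integer"):
            generate_recording(_cfg(duration=10.0001), seed=0)


class TestArtifacts:
    def _rec(self):
        return generate_recording(_cfg(duration=20.0), seed=9)

    def test_empty_spec_is_identity(self):
        rec = self._rec()
        out, log = inject_artifacts(rec, [])
        assert (out.data == rec.data).all() and log == []

    def test_spike_touches_only_logged_samples(self):
        rec = self._rec()
        out, log = inject_artifacts(
            rec, [Artifact("spike", "ch3", onset=10.0, amplitude=150.0)]
        )
        changed = np.argwhere(out.data != rec.data)
        (entry,) = log
        assert {tuple(c) for c in changed} == {(3, entry["start_sample"])}
        assert entry["start_sample"] == int(10.0 * rec.fs)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            inject_artifacts(
                self._rec(), [Artifact("spike", "ch0", onset=1.0, amplitude=-5.0)]
            )

    def test_onset_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            inject_artifacts(
                self._rec(), [Artifact("step", "ch0", onset=999.0, amplitude=10.0)]
            )

    def test_burst_peak_to_peak_amplitude(self):
        rec = self._rec()
        out, log = inject_artifacts(
            rec,
            [Artifact("burst", "ch1", onset=5.0, amplitude=200.0, duration=0.5)],
        )
        seg = out.data[1] - rec.data[1]
        assert np.ptp(seg) == pytest.approx(200.0, rel=0.01)


class TestGenerateStudy:
    def test_recording_count_and_shared_geometry(self):
        study = generate_study(_cfg(duration=10.0), n_per_group=3, seed=1)
        recs = list(study.recordings())
        assert len(recs) == 12  # 2 groups x 3 subjects x 2 conditions
        fs = {rec.fs for *_, rec in recs}
        labs = {rec.labels for *_, rec in recs}
        assert fs == {256.0} and labs == {LAB8}

    def test_thirteen_per_group_gives_52_recordings(self):
        study = generate_study(
            _cfg(duration=5.0, fs=128.0), n_per_group=13, seed=2
        )
        assert study.n_recordings == 52

    def test_study_determinism(self):
        cfg = _cfg(duration=5.0)
        a = generate_study(cfg, n_per_group=2, seed=5)
        b = generate_study(cfg, n_per_group=2, seed=5)
        ra = a.groups["control"][a.subjects("control")[0]]["pre"].data
        rb = b.groups["control"][b.subjects("control")[0]]["pre"].data
        assert (ra == rb).all()

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_study(_cfg(), n_per_group=1, seed=0)

    def test_treated_post_power_moves_in_effect_direction(self):
        cfg = _cfg(duration=30.0)
        study = generate_study(cfg, n_per_group=4, seed=7)

        def group_band_means(group, cond):
            vals = []
            for sid in study.subjects(group):
                rec = study.groups[group][sid][cond]
                vals.append(band_power_table(segment(rec, 5.0)).mean(axis=(0, 1)))
            return np.mean(vals, axis=0)

        chiro_diff = group_band_means("chiropractic", "post") - group_band_means(
            "chiropractic", "pre"
        )
        ctrl_diff = group_band_means("control", "post") - group_band_means(
            "control", "pre"
        )
        for band in ("delta", "theta"):
            assert chiro_diff[BAND_NAMES.index(band)] < 0
        assert chiro_diff[BAND_NAMES.index("beta2")] > 0
        assert np.abs(ctrl_diff).max() < np.abs(chiro_diff).max()

    def test_study_roundtrip_to_disk(self, tmp_path):
        study = generate_study(_cfg(duration=5.0), n_per_group=2, seed=3)
        out = study.save(tmp_path / "study")
        files = sorted(p.name for p in out.glob("*.f32"))
        assert len(files) == 8
        assert (out / "ground_truth.json").exists()


def test_theta_effect_detected_by_cluster_test():
    """A 50% theta power reduction is flagged by the downstream cluster test
    (p < 0.05) in at least 80% of simulated studies."""
    from eegperm.cluster import build_adjacency, cluster_permutation_test
    from eegperm.montage import Montage, default_montage

    m62 = default_montage()
    labels = m62.labels[:20]
    montage = Montage(labels=labels, coords=m62.coords[:20])
    adjacency = build_adjacency(montage)
    cfg = SynthConfig(
        n_channels=20, fs=256.0, duration=20.0, labels=labels,
        effect={"theta": 0.5},
    )
    theta = BAND_NAMES.index("theta")
    # n = 8 subjects: the sign-flip null needs 2/2^n < 0.05, which rules
    # out groups smaller than 7.
    hits = 0
    n_studies = 20
    for s in range(n_studies):
        study = generate_study(cfg, n_per_group=8, seed=100 + s)
        pre, post = [], []
        for sid in study.subjects("chiropractic"):
            conds = study.groups["chiropractic"][sid]
            pre.append(
                band_power_table(segment(conds["pre"], 5.0)).mean(0)[:, theta]
            )
            post.append(
                band_power_table(segment(conds["post"], 5.0)).mean(0)[:, theta]
            )
        res = cluster_permutation_test(
            np.array(pre), np.array(post), adjacency, n_perm=500, seed=s
        )
        hits += res.min_p() < 0.05
    assert hits >= 0.8 * n_studies
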