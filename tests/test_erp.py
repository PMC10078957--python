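"""Cluster formation, consecutive averaging, downsampling, difference waves."""

import numpy as np
import pytest

from serpbci import erp
from serpbci.erp import (
    CLUSTER_KEYS,
    DiffWaveform,
    InsufficientDataError,
    SerpWaveform,
    assign_clusters,
    average_group,
    balance_and_group,
    diff_serp,
    downsample,
    grand_diff,
    serp_matrix,
)
from serpbci.preprocess import baseline_correct, epoch, reject_artifacts
from serpbci.protocol import Location, ProtocolConfig, generate_schedule
from serpbci.synth import CHANNELS, SubjectModel, render_template, simulate_recording


@pytest.fixture(scope="module")
def clean_clusters():
    sched = generate_schedule(ProtocolConfig(n_blocks=2, seed=3))
    subject = SubjectModel(attention_gain=2.0, noise_sd_uV=0.0, blink_rate_hz=0.0)
    rec = simulate_recording(sched, subject)
    eps = reject_artifacts(baseline_correct(epoch(rec)))
    return assign_clusters(eps), subject


class TestAssignClusters:
    def test_full_default_schedule_gives_450_per_cluster(self):
        sched = generate_schedule(ProtocolConfig(seed=2))
        subject = SubjectModel(attention_gain=1.0, noise_sd_uV=0.0, blink_rate_hz=0.0)
        rec = simulate_recording(sched, subject)
        clusters = assign_clusters(epoch(rec))
        assert clusters.counts() == {k: 450 for k in CLUSTER_KEYS}

    def test_partition_is_exhaustive_and_disjoint(self, clean_clusters):
        clusters, _ = clean_clusters
        counts = clusters.counts()
        assert sum(counts.values()) == 600  # 2 blocks x 300, none rejected
        for key, eps in clusters.clusters.items():
            att, stim = erp.CLUSTER_DEF[key]
            assert all(
                e.event.attended_location is att and e.event.location is stim
                for e in eps
            )


class TestBalanceAndGroup:
    def _fake_clusters(self, sizes):
        from serpbci.preprocess import Epoch
        from serpbci.protocol import StimulusEvent

        clusters = {}
        for key, n in zip(CLUSTER_KEYS, sizes):
            att, stim = erp.CLUSTER_DEF[key]
            clusters[key] = [
                erp.Epoch(np.zeros((6, 600)), StimulusEvent(i, stim, 1, 1, att))
                for i in range(n)
            ]
        return erp.ClusterSet(clusters, CHANNELS)

    def test_equal_sizes_full_grouping(self):
        grouped = balance_and_group(self._fake_clusters([450] * 4), 10)
        assert all(len(g) == 45 for g in grouped.values())

    def test_unequal_sizes_truncate_to_common_minimum(self):
        grouped = balance_and_group(self._fake_clusters([430, 442, 418, 450]), 10)
        assert all(len(g) == 41 for g in grouped.values())  # floor(418/10)
        assert all(all(len(gr) == 10 for gr in g) for g in grouped.values())

    def test_truncation_drops_last_trials(self):
        clusters = self._fake_clusters([25, 25, 25, 20])
        grouped = balance_and_group(clusters, 10)  # m = 2 -> keep first 20
        first = grouped["ADSD"]
        kept_onsets = [e.event.onset_sample for grp in first for e in grp]
        assert kept_onsets == list(range(20))

    def test_groups_are_consecutive_non_overlapping(self):
        grouped = balance_and_group(self._fake_clusters([31] * 4), 5)
        for g in grouped.values():
            onsets = [e.event.onset_sample for grp in g for e in grp]
            assert onsets == list(range(30))

    def test_too_small_cluster_raises(self):
        with pytest.raises(InsufficientDataError, match="ADSD"):
            balance_and_group(self._fake_clusters([9, 450, 450, 450]), 10)


class TestAverageDownsample:
    def test_identical_trials_average_to_themselves(self, clean_clusters):
        clusters, subject = clean_clusters
        group = clusters.clusters["ADSD"][:5]
        w = average_group(group, "C3", CHANNELS)
        np.testing.assert_allclose(w.values, group[0].data[0, 120:])

    def test_average_matches_loop_sum_oracle(self):
        rng = np.random.default_rng(0)
        from serpbci.preprocess import Epoch
        from serpbci.protocol import StimulusEvent

        group = [
            erp.Epoch(rng.standard_normal((6, 600)), StimulusEvent(i, Location.D, 1, 1, Location.D))
            for i in range(5)
        ]
        w = average_group(group, "Cz", CHANNELS)
        ci = CHANNELS.index("Cz")
        oracle = np.zeros(480)
        for ep in group:  # naive accumulation
            oracle += ep.data[ci, 120:]
        oracle /= len(group)
        np.testing.assert_allclose(w.values, oracle)

    def test_downsample_length_and_rate(self):
        w = SerpWaveform("C3", np.zeros(480), 10, "ADSD", 0)
        d = downsample(w)
        assert len(d.values) == 60
        assert d.rate_hz == 150.0

    def test_downsample_ramp_keeps_every_eighth(self):
        w = SerpWaveform("C3", np.arange(480.0), 10, "ADSD", 0)
        np.testing.assert_array_equal(downsample(w).values, np.arange(0.0, 480.0, 8.0))

    def test_downsample_constant_preserved(self):
        w = SerpWaveform("C3", np.full(480, 2.5), 3, "ADSD", 0)
        assert np.all(downsample(w).values == 2.5)

    def test_non_divisible_length_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            downsample(SerpWaveform("C3", np.zeros(100), 3, "ADSD", 0))


class TestDifferenceWaves:
    def _wave(self, values, cluster="ADSD"):
        return SerpWaveform("C3", np.asarray(values, float), 10, cluster, 0)

    def test_identical_waveforms_cancel(self):
        w = self._wave(np.arange(60))
        d = diff_serp(w, self._wave(np.arange(60), "ADSV"))
        assert np.all(d.values == 0)
        assert d.condition == "AD"

    def test_zero_subtrahend_is_identity(self):
        w = self._wave(np.random.default_rng(1).standard_normal(60))
        d = diff_serp(w, self._wave(np.zeros(60), "ADSV"))
        np.testing.assert_array_equal(d.values, w.values)

    def test_antisymmetric_pair_doubles(self):
        v = np.sin(np.linspace(0, 3, 60))
        d = diff_serp(self._wave(v, "AVSD"), self._wave(-v, "AVSV"))
        np.testing.assert_allclose(d.values, 2 * v)
        assert d.condition == "AV"

    def test_condition_mismatch_raises(self):
        with pytest.raises(ValueError, match="condition"):
            diff_serp(self._wave(np.zeros(60), "ADSD"), self._wave(np.zeros(60), "AVSV"))

    def test_grand_diff_of_identical_class_means_is_zero(self):
        d = DiffWaveform("C3", np.ones(60), "AD", 10)
        e = DiffWaveform("C3", np.ones(60), "AV", 10)
        assert np.all(grand_diff([d, d], [e]).values == 0)

    def test_grand_diff_singletons_plain_subtraction(self):
        rng = np.random.default_rng(2)
        a = DiffWaveform("C3", rng.standard_normal(60), "AD", 10)
        b = DiffWaveform("C3", rng.standard_normal(60), "AV", 10)
        np.testing.assert_allclose(grand_diff([a], [b]).values, a.values - b.values)

    def test_grand_diff_linearity(self):
        rng = np.random.default_rng(3)
        ads = [DiffWaveform("C3", rng.standard_normal(60), "AD", 10) for _ in range(3)]
        avs = [DiffWaveform("C3", rng.standard_normal(60), "AV", 10) for _ in range(2)]
        base = grand_diff(ads, avs).values
        scaled = grand_diff(
            [DiffWaveform("C3", 2 * d.values, "AD", 10) for d in ads],
            [DiffWaveform("C3", 2 * d.values, "AV", 10) for d in avs],
        ).values
        np.testing.assert_allclose(scaled, 2 * base)

    def test_grand_diff_empty_raises(self):
        with pytest.raises(ValueError):
            grand_diff([], [DiffWaveform("C3", np.zeros(60), "AV", 10)])


def test_noise_free_attention_contrast_matches_construction(clean_clusters):
    """With gain g on the attended site, the class contrast of difference
    waves equals (g-1) x (template_D + template_V) on the decimated grid."""
    clusters, subject = clean_clusters
    g = subject.attention_gain
    grouped = balance_and_group(clusters, 10)
    serps = serp_matrix(grouped, "C3", CHANNELS)
    diffs_ad = serps["ADSD"] - serps["ADSV"]
    diffs_av = serps["AVSD"] - serps["AVSV"]
    adav = diffs_ad.mean(axis=0) - diffs_av.mean(axis=0)
    t_d = render_template(subject.template_D)[::8]
    t_v = render_template(subject.template_V)[::8]
    gain_c3 = subject.template_D.gain_map["C3"]
    np.testing.assert_allclose(adav, (g - 1) * gain_c3 * (t_d + t_v), atol=1e-10)


def test_residual_noise_ordering_sep3_sep5_sep10():
    """1/sqrt(n): residual sd around the template shrinks with averaging."""
    sched = generate_schedule(ProtocolConfig(n_blocks=2, seed=9))
    subject = SubjectModel(attention_gain=1.0, noise_sd_uV=8.0, blink_rate_hz=0.0, seed=9)
    rec = simulate_recording(sched, subject)
    eps = reject_artifacts(baseline_correct(epoch(rec)))
    clusters = assign_clusters(eps)
    resid = {}
    for n in (3, 5, 10):
        grouped = balance_and_group(clusters, n)
        serps = serp_matrix(grouped, "C3", CHANNELS)
        all_rows = np.vstack(list(serps.values()))
        resid[n] = np.mean(np.std(all_rows - all_rows.mean(axis=0), axis=1))
    assert resid[10] < resid[5] < resid[3]
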