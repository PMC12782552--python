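"""Spike detection, embedding, clustering, template matching, curation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from crawlkit import spikesort, synth
from crawlkit.spikesort import (
    EventSet,
    cluster_events,
    curate,
    detect_spikes,
    embed_waveforms,
    match_event_times,
    match_templates,
    replay_log,
    sort_trace,
)
from crawlkit.synth import make_template, render_extracellular
from crawlkit.timeseries import TimeSeries


class TestDetectSpikes:
    def test_zero_trace_no_events(self):
        ev = detect_spikes(TimeSeries(np.zeros(10_000), rate=10_000))
        assert ev.n == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(TimeSeries(np.zeros(100), rate=10_000), threshold_k=0)

    def test_recovers_noiseless_insertions(self):
        tpl = make_template(12.0, rate=10_000)
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.05, 4.95, 50))
        times = times[np.r_[True, np.diff(times) > 0.01]]
        trace, _ = render_extracellular(
            [(times, tpl)], rate=10_000, noise_sd=0.0, duration=5.0
        )
        ev = detect_spikes(trace)
        m = match_event_times(ev.times, times, tol=2.5 / 10_000)
        assert ev.n == times.size
        assert np.all(m >= 0)  # every insertion found within ~1 sample

    def test_false_positives_below_excursion_count_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, 200_000)
        ev = detect_spikes(TimeSeries(x, rate=10_000), threshold_k=5.0)
        # oracle: brute-force count of |x| excursions beyond 5 true SD
        above = np.abs(x) > 5.0
        n_excursions = np.sum(np.diff(above.astype(int)) == 1) + above[0]
        assert ev.n <= n_excursions

    def test_both_polarities_detected(self):
        pos = make_template(10.0, rate=10_000, polarity=1)
        neg = make_template(10.0, rate=10_000, polarity=-1)
        trace, _ = render_extracellular(
            [(np.array([0.05]), pos), (np.array([0.15]), neg)],
            rate=10_000,
            noise_sd=0.0,
            duration=0.25,
        )
        ev = detect_spikes(trace)
        assert ev.n == 2


class TestEmbedWaveforms:
    def _families(self, rng, n=60):
        base = make_template(80.0, rate=10_000)
        small = make_template(8.0, rate=10_000, width_ms=0.7)
        wf = np.concatenate(
            [
                np.tile(base, (n, 1)),
                np.tile(small[: base.size] if small.size >= base.size else
                        np.pad(small, (0, base.size - small.size)), (n, 1)),
            ]
        )
        return wf + rng.normal(0, 0.01, wf.shape)

    def test_two_families_separate(self, rng):
        wf = self._families(rng)
        emb = embed_waveforms(wf, seed=0)
        n = wf.shape[0] // 2
        c1, c2 = emb[:n].mean(axis=0), emb[n:].mean(axis=0)
        spread = max(
            np.linalg.norm(emb[:n] - c1, axis=1).mean(),
            np.linalg.norm(emb[n:] - c2, axis=1).mean(),
        )
        assert np.linalg.norm(c1 - c2) > spread

    def test_deterministic_under_seed(self, rng):
        wf = self._families(rng)
        a = embed_waveforms(wf, seed=0)
        b = embed_waveforms(wf, seed=0)
        assert np.array_equal(a, b)

    def test_identical_waveforms_stay_compact(self, rng):
        tpl = make_template(10.0, rate=10_000)
        wf = np.tile(tpl, (40, 1))
        emb = embed_waveforms(wf, seed=0)
        ctrl = embed_waveforms(rng.normal(0, 1, wf.shape), seed=0)
        d_same = np.linalg.norm(emb - emb.mean(axis=0), axis=1).mean()
        d_ctrl = np.linalg.norm(ctrl - ctrl.mean(axis=0), axis=1).mean()
        assert d_same < d_ctrl

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            embed_waveforms(np.zeros((1, 31)))


class TestClusterAndMatch:
    def test_benchmark_ari(self, std_episode):
        res = sort_trace(std_episode.trace, seed=0)
        true_lab = np.full(res.events.n, -1)
        for ui, uid in enumerate(std_episode.spikes):
            m = match_event_times(res.events.times, std_episode.spikes[uid])
            true_lab[m[m >= 0]] = ui
        ok = true_lab >= 0
        assert adjusted_rand_score(true_lab[ok], res.assignments[ok]) >= 0.9

    def test_single_unit_one_cluster(self):
        tpl = make_template(80.0, rate=10_000)
        wf = np.tile(tpl, (30, 1))
        emb = embed_waveforms(wf, seed=0)
        labels, clusters = cluster_events(emb, wf, min_cluster_size=10)
        assert len(clusters) == 1
        assert np.all(labels == 0)

    def test_templates_pairwise_distinguishable(self, std_episode):
        res = sort_trace(std_episode.trace, seed=0)
        ids = res.unit_ids()
        assert len(ids) == 3
        from crawlkit.spikesort import _distances

        tpl = np.stack([res.clusters[c].template for c in ids])
        d = _distances(tpl, tpl)
        spread = [
            np.median(
                _distances(
                    res.events.waveforms[res.clusters[c].members], tpl[j : j + 1]
                )
            )
            for j, c in enumerate(ids)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert d[i, j] > 3 * max(spread[i], spread[j])

    def test_exact_template_distance_zero(self):
        tpl = make_template(10.0, rate=10_000)
        events = EventSet(np.array([0.1]), tpl[None, :])
        clusters = {
            0: spikesort.Cluster(0, np.array([0]), tpl),
            1: spikesort.Cluster(1, np.array([], dtype=int), -tpl),
        }
        res = match_templates(events, clusters)
        assert res.assignments[0] == 0

    def test_noiseless_matching_is_perfect(self):
        t1 = make_template(10.0, rate=10_000, width_ms=1.2)
        t2 = make_template(20.0, rate=10_000, width_ms=0.8, polarity=1)
        rng = np.random.default_rng(4)
        times1 = np.sort(rng.uniform(0.1, 9.9, 40))
        times2 = np.sort(rng.uniform(0.1, 9.9, 40))
        trace, _ = render_extracellular(
            [(times1, t1), (times2, t2)], rate=10_000, noise_sd=0.0, duration=10.0
        )
        res = sort_trace(trace, seed=0, min_cluster_size=10)
        for times, _tpl in ((times1, t1), (times2, t2)):
            m = match_event_times(res.events.times, times)
            got = res.assignments[m[m >= 0]]
            # all spikes of one source unit land in one accepted cluster
            assert m.min() >= 0 or np.sum(m >= 0) >= times.size - 2
            assert len(set(got.tolist())) == 1

    def test_no_clusters_means_noise_pool(self):
        events = EventSet(np.array([0.1]), make_template(5.0)[None, :])
        with pytest.warns(UserWarning):
            res = match_templates(events, {})
        assert np.all(res.assignments == -1)


class TestCuration:
    @pytest.fixture()
    def sorted_result(self, std_episode):
        return sort_trace(std_episode.trace, seed=0)

    def test_merge_conserves_events(self, sorted_result):
        ids = sorted_result.unit_ids()[:2]
        n_before = sum((sorted_result.assignments == c).sum() for c in ids)
        out = curate(sorted_result, "merge", ids=ids)
        new_id = out.log[-1]["new_id"]
        assert (out.assignments == new_id).sum() == n_before
        st = out.spike_times(new_id)
        assert np.all(np.diff(st) >= 0)

    def test_split_recovers_deliberately_merged_pair(self, std_episode, sorted_result):
        ids = sorted_result.unit_ids()
        merged = curate(sorted_result, "merge", ids=ids[:2])
        new_id = merged.log[-1]["new_id"]
        split = curate(merged, "split", id=new_id, k=2, seed=0)
        # score the split against the generator ledger for those two clusters
        true_lab = np.full(split.events.n, -1)
        for ui, uid in enumerate(std_episode.spikes):
            m = match_event_times(split.events.times, std_episode.spikes[uid])
            true_lab[m[m >= 0]] = ui
        sel = np.isin(split.assignments, split.log[-1]["new_ids"]) & (true_lab >= 0)
        assert adjusted_rand_score(true_lab[sel], split.assignments[sel]) >= 0.9

    def test_discard_then_replay_is_identical(self, sorted_result):
        cid = sorted_result.unit_ids()[0]
        curated = curate(sorted_result, "discard", id=cid)
        replayed = replay_log(sorted_result, curated.log[len(sorted_result.log):])
        assert np.array_equal(replayed.assignments, curated.assignments)
        assert replayed.log == curated.log

    def test_event_conservation_through_sequence(self, sorted_result):
        out = sorted_result
        out = curate(out, "merge", ids=out.unit_ids()[:2])
        out = curate(out, "discard", id=out.unit_ids()[0])
        n_assigned = (out.assignments >= 0).sum()
        n_noise = (out.assignments == -1).sum()
        assert n_assigned + n_noise == out.events.n

    def test_bad_split_rejected(self, sorted_result):
        cid = sorted_result.unit_ids()[0]
        with pytest.raises(ValueError):
            curate(sorted_result, "split", id=cid, k=1)
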