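"""Template-matching spike sorter for extracellular nerve recordings.

Stages: threshold detection on the rectified trace (robust MAD noise
estimate), a 2-D t-SNE embedding of the spike waveforms, density-based
clustering on the embedding, template matching of every event to the
cluster mean waveforms, and a replayable split/merge/discard curation log.

Nerve units differ mainly by spike amplitude, so template distances are
plain Euclidean after peak alignment and baseline subtraction — no
amplitude normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.manifold import TSNE

from .timeseries import TimeSeries

__all__ = [
    "EventSet",
    "Cluster",
    "SortResult",
    "detect_spikes",
    "embed_waveforms",
    "cluster_events",
    "match_templates",
    "merge_similar_clusters",
    "curate",
    "replay_log",
    "sort_trace",
    "match_event_times",
]

log = logging.getLogger(__name__)


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD via the median absolute deviation (MAD / 0.6745)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


@dataclass
class EventSet:
    """Detected spike events on one channel: times plus aligned waveforms."""

    times: np.ndarray  # (n,) seconds, sorted
    waveforms: np.ndarray  # (n, w), extremum-centered
    channel: str = "DP"
    rate: float = 10_000.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.times.size != self.waveforms.shape[0]:
            raise ValueError("times and waveforms must align")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def peak_amplitude(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        c = self.waveforms.shape[1] // 2
        return self.waveforms[:, c]


@dataclass
class Cluster:
    """A putative single unit: member events and their mean waveform."""

    id: int
    members: np.ndarray  # event indices into the EventSet
    template: np.ndarray
    accepted: bool = True
    discarded: bool = False
    split_from: int | None = None
    merged_from: tuple[int, ...] | None = None


@dataclass
class SortResult:
    """Output of template matching plus any curation applied to it.

    ``assignments[i]`` is the accepted cluster id of event ``i`` or ``-1``
    for the noise pool.  ``log`` is an ordered, replayable record of
    curation actions.
    """

    events: EventSet
    clusters: dict[int, Cluster]
    assignments: np.ndarray
    log: list[dict] = field(default_factory=list)

    def unit_ids(self) -> list[int]:
        return sorted(
            cid
            for cid, c in self.clusters.items()
            if c.accepted and not c.discarded
        )

    def spike_times(self, cid: int) -> np.ndarray:
        return np.sort(self.events.times[self.assignments == cid])

    def copy(self) -> "SortResult":
        return SortResult(
            events=self.events,
            clusters={
                cid: replace(c, members=c.members.copy(), template=c.template.copy())
                for cid, c in self.clusters.items()
            },
            assignments=self.assignments.copy(),
            log=[dict(e) for e in self.log],
        )


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------

def detect_spikes(
    trace: TimeSeries,
    threshold_k: float = 5.0,
    window: float = 0.003,
    refractory: float | None = None,
    channel: str = "DP",
) -> EventSet:
    """Detect spikes as rectified local extrema above ``threshold_k`` x noise SD.

    Both polarities are detected (nerve spikes are biphasic).  Events closer
    than ``refractory`` (default: the waveform window, so the trailing lobe
    of one biphasic spike never registers twice) are deduplicated keeping the
    larger extremum, and
    each waveform is a ``window``-long snippet centered on its extremum.
    Events whose window would clip a trace edge are dropped.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    if refractory is None:
        refractory = window
    x = trace.values
    sd = robust_noise_sd(x)
    half = max(int(round(window * trace.rate / 2)), 1)
    if sd == 0:
        thr = 0.0
        if np.all(x == x[0]):
            return EventSet(
                np.empty(0), np.empty((0, 2 * half + 1)), channel, trace.rate
            )
    else:
        thr = threshold_k * sd
    dist = max(int(round(refractory * trace.rate)), 1)
    peaks, props = find_peaks(np.abs(x), height=max(thr, 1e-12), distance=dist)
    keep = (peaks >= half) & (peaks < x.size - half)
    peaks = peaks[keep]
    # canonical alignment: a biphasic spike with comparable lobes may be
    # caught on either extremum; recenter on the earliest lobe within 70%
    # of the window maximum so every firing of a unit aligns the same way
    if peaks.size:
        realigned = []
        for p in peaks:
            seg = np.abs(x[p - half : p + half + 1])
            cand, _ = find_peaks(seg, height=0.7 * seg.max())
            if cand.size == 0:
                cand = np.array([int(np.argmax(seg))])
            c = p - half + cand[0]
            realigned.append(min(max(c, half), x.size - half - 1))
        peaks = np.asarray(realigned)
        # realignment can collapse neighbours onto one lobe; dedup again
        keep_mask = np.ones(peaks.size, dtype=bool)
        for i in range(1, peaks.size):
            if peaks[i] - peaks[i - 1] < dist:
                weaker = i if np.abs(x[peaks[i]]) < np.abs(x[peaks[i - 1]]) else i - 1
                keep_mask[weaker] = False
        peaks = np.unique(peaks[keep_mask])
    wf = np.stack([x[p - half : p + half + 1] for p in peaks]) if peaks.size else (
        np.empty((0, 2 * half + 1))
    )
    return EventSet(
        times=trace.t0 + peaks / trace.rate,
        waveforms=wf,
        channel=channel,
        rate=trace.rate,
    )


# ----------------------------------------------------------------------
# embedding and clustering
# ----------------------------------------------------------------------

def embed_waveforms(
    waveforms: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding of the event waveforms.

    Deterministic for a fixed seed (PCA initialization).  Perplexity is
    auto-reduced (and logged) when there are too few events.  The embedding
    is used only for clustering and visual curation, never for timing.
    """
    waveforms = np.atleast_2d(waveforms)
    n = waveforms.shape[0]
    if n < 2:
        raise ValueError("need at least 2 events to embed")
    max_p = (n - 1) / 3.0
    if perplexity > max_p:
        perplexity = max(max_p, 1.0)
        log.info("perplexity auto-reduced to %.1f for %d events", perplexity, n)
    scale = float(np.max(np.abs(waveforms))) or 1.0
    n_unique = np.unique(waveforms, axis=0).shape[0]
    if n_unique == 1:
        # fully degenerate input: a single tight deterministic cloud
        return np.random.default_rng(seed).normal(0.0, 1e-6, size=(n, 2))
    if n_unique < n:
        # exact duplicates crash Barnes-Hut t-SNE; break ties imperceptibly
        waveforms = waveforms + np.random.default_rng(seed).normal(
            0.0, 1e-9 * scale, size=waveforms.shape
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        ).fit_transform(waveforms)
    return np.asarray(emb, dtype=float)


def _baseline_subtract(wf: np.ndarray) -> np.ndarray:
    """Remove each waveform's edge baseline, preserving amplitude."""
    wf = np.atleast_2d(wf)
    q = max(wf.shape[1] // 5, 1)
    base = np.mean(np.concatenate([wf[:, :q], wf[:, -q:]], axis=1), axis=1)
    return wf - base[:, None]


def cluster_events(
    embedding: np.ndarray,
    waveforms: np.ndarray,
    min_cluster_size: int = 20,
) -> tuple[np.ndarray, dict[int, Cluster]]:
    """Density-based grouping of events on the 2-D embedding.

    Every event receives a label (noise is ``-1``); templates are per-cluster
    mean waveforms.  Degenerate inputs (fewer events than the minimum
    cluster size, or no density cluster found) collapse to one cluster.
    """
    embedding = np.atleast_2d(embedding)
    waveforms = np.atleast_2d(waveforms)
    n = embedding.shape[0]
    if n == 0:
        return np.empty(0, dtype=int), {}
    if n <= min_cluster_size:
        labels = np.zeros(n, dtype=int)
    else:
        labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(
            embedding
        )
        if not np.any(labels >= 0):
            labels = np.zeros(n, dtype=int)
    clusters: dict[int, Cluster] = {}
    for cid in sorted(set(labels[labels >= 0])):
        members = np.flatnonzero(labels == cid)
        template = waveforms[members].mean(axis=0)
        clusters[int(cid)] = Cluster(int(cid), members, template)
    return labels, clusters


# ----------------------------------------------------------------------
# template matching
# ----------------------------------------------------------------------

def _distances(
    waveforms: np.ndarray, templates: np.ndarray, max_shift: int = 2
) -> np.ndarray:
    """RMS Euclidean distance of each waveform to each template.

    Peak alignment: each template may slide by up to ``max_shift`` samples
    (detection centers waveforms on their extremum only to one-sample
    precision) and the best alignment counts.
    """
    wf = _baseline_subtract(waveforms)
    tp = _baseline_subtract(templates)
    best = None
    w = wf.shape[1]
    lo = max_shift
    core = slice(lo, w - lo) if w > 2 * lo else slice(None)
    for s in range(-max_shift, max_shift + 1):
        tps = np.roll(tp, s, axis=1)
        d = wf[:, None, core] - tps[None, :, core]
        dd = np.sqrt(np.mean(d * d, axis=2))
        best = dd if best is None else np.minimum(best, dd)
    return best


def match_templates(
    events: EventSet,
    clusters: dict[int, Cluster],
    ceiling_factor: float = 4.0,
) -> SortResult:
    """Assign every event to the nearest template, or to the noise pool.

    The acceptance ceiling per cluster is ``ceiling_factor`` x the median
    distance of that cluster's own members to their template (with a small
    numerical floor so exact matches on noiseless data are always accepted).
    """
    active = {cid: c for cid, c in clusters.items() if c.accepted and not c.discarded}
    if not active:
        warnings.warn("no accepted clusters; all events go to the noise pool")
        return SortResult(
            events, dict(clusters), np.full(events.n, -1, dtype=int)
        )
    cids = sorted(active)
    templates = np.stack([active[c].template for c in cids])
    d = _distances(events.waveforms, templates)
    best = np.argmin(d, axis=1)
    best_d = d[np.arange(events.n), best]

    ceilings = np.empty(len(cids))
    for j, cid in enumerate(cids):
        members = active[cid].members
        med = (
            float(np.median(_distances(events.waveforms[members], templates[j : j + 1])))
            if members.size
            else 0.0
        )
        scale = float(np.max(np.abs(templates[j])))
        ceilings[j] = max(ceiling_factor * med, 0.05 * scale, 1e-12)

    assignments = np.where(
        best_d <= ceilings[best], np.asarray(cids)[best], -1
    ).astype(int)

    out_clusters = {}
    for cid, c in clusters.items():
        if cid in active:
            members = np.flatnonzero(assignments == cid)
            out_clusters[cid] = replace(c, members=members)
        else:
            out_clusters[cid] = replace(c)
    return SortResult(events, out_clusters, assignments)


# ----------------------------------------------------------------------
# curation
# ----------------------------------------------------------------------

def curate(result: SortResult, action: str, **kwargs) -> SortResult:
    """Apply one curation action, appending it to the replayable log.

    Actions: ``split`` (2-means on member waveforms by default),
    ``merge`` (event counts conserved, times re-sorted implicitly),
    ``discard`` (members go to the noise pool).
    """
    out = result.copy()
    if action == "merge":
        ids = tuple(int(i) for i in kwargs["ids"])
        for cid in ids:
            if cid not in out.clusters:
                raise KeyError(f"unknown cluster {cid}")
        new_id = max(out.clusters) + 1
        members = np.sort(
            np.concatenate([out.clusters[c].members for c in ids])
        )
        template = out.events.waveforms[members].mean(axis=0) if members.size else (
            out.clusters[ids[0]].template
        )
        out.clusters[new_id] = Cluster(
            new_id, members, template, merged_from=ids
        )
        for cid in ids:
            out.clusters[cid].accepted = False
        out.assignments[np.isin(out.assignments, ids)] = new_id
        out.log.append({"action": "merge", "ids": list(ids), "new_id": new_id})
    elif action == "split":
        cid = int(kwargs["id"])
        k = int(kwargs.get("k", 2))
        seed = int(kwargs.get("seed", 0))
        if cid not in out.clusters:
            raise KeyError(f"unknown cluster {cid}")
        if k < 2:
            raise ValueError("split requires k >= 2")
        members = out.clusters[cid].members
        if members.size < k:
            raise ValueError("cannot split a cluster into fewer than 2 nonempty parts")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        sub = km.fit_predict(out.events.waveforms[members])
        if len(set(sub)) < k:
            raise ValueError("split produced an empty part")
        base = max(out.clusters) + 1
        new_ids = []
        for j in range(k):
            mj = members[sub == j]
            out.clusters[base + j] = Cluster(
                base + j,
                mj,
                out.events.waveforms[mj].mean(axis=0),
                split_from=cid,
            )
            out.assignments[mj] = base + j
            new_ids.append(base + j)
        out.clusters[cid].accepted = False
        out.log.append(
            {"action": "split", "id": cid, "k": k, "seed": seed, "new_ids": new_ids}
        )
    elif action == "discard":
        cid = int(kwargs["id"])
        if cid not in out.clusters:
            raise KeyError(f"unknown cluster {cid}")
        out.assignments[out.assignments == cid] = -1
        out.clusters[cid].discarded = True
        out.clusters[cid].members = np.empty(0, dtype=int)
        out.log.append({"action": "discard", "id": cid})
    else:
        raise ValueError(f"unknown curation action {action!r}")
    return out


def _rate_correlation(a: np.ndarray, b: np.ndarray, bin_s: float = 1.0) -> float:
    """Pearson correlation of two units' binned spike counts."""
    if a.size == 0 or b.size == 0:
        return 0.0
    lo = min(a[0], b[0])
    hi = max(a[-1], b[-1])
    edges = np.arange(lo, hi + bin_s, bin_s)
    if edges.size < 3:
        return 0.0
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    if np.std(ca) == 0 or np.std(cb) == 0:
        return 0.0
    return float(np.corrcoef(ca, cb)[0, 1])


def merge_similar_clusters(result: SortResult, merge_factor: float = 3.0) -> SortResult:
    """Merge accepted clusters whose templates are indistinguishable.

    Pairs whose shift-invariant template distance falls below
    ``merge_factor`` x the larger of the two within-cluster median
    distances are merged (transitively), through the ordinary curation
    log.  This automates the merge half of manual curation: density
    clustering on a t-SNE plane routinely splits one unit into islands
    that differ only by sub-sample alignment.  ``_rate_correlation`` is
    available as an additional line of evidence when curating by hand.
    """
    out = result
    while True:
        ids = out.unit_ids()
        if len(ids) < 2:
            return out
        templates = np.stack([out.clusters[c].template for c in ids])
        d = _distances(templates, templates)
        spread = []
        for j, cid in enumerate(ids):
            members = out.clusters[cid].members
            if members.size:
                dm = _distances(out.events.waveforms[members], templates[j : j + 1])
                spread.append(float(np.median(dm)))
            else:
                spread.append(0.0)
        merged_any = False
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                thresh = merge_factor * max(spread[i], spread[j])
                if thresh > 0 and d[i, j] < thresh:
                    out = curate(out, "merge", ids=[ids[i], ids[j]])
                    merged_any = True
                    break
            if merged_any:
                break
        if not merged_any:
            return out


def replay_log(result: SortResult, log_entries: list[dict]) -> SortResult:
    """Re-apply a curation log to an uncurated result, deterministically."""
    out = result.copy()
    for entry in log_entries:
        kwargs = {k: v for k, v in entry.items() if k not in ("action", "new_id", "new_ids")}
        out = curate(out, entry["action"], **kwargs)
    return out


# ----------------------------------------------------------------------
# end-to-end convenience
# ----------------------------------------------------------------------

def sort_trace(
    trace: TimeSeries,
    threshold_k: float = 5.0,
    window: float = 0.003,
    seed: int = 0,
    min_cluster_size: int = 20,
    max_embed: int = 1000,
    channel: str = "DP",
) -> SortResult:
    """Detect -> embed -> cluster -> template-match, in one call.

    When more than ``max_embed`` events are detected, the embedding and
    clustering run on a seeded random subsample; template matching then
    assigns every detected event, so no spikes are lost to the cap.
    """
    events = detect_spikes(trace, threshold_k=threshold_k, window=window, channel=channel)
    if events.n < 2:
        return SortResult(events, {}, np.full(events.n, -1, dtype=int))
    if events.n > max_embed:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(events.n, size=max_embed, replace=False))
    else:
        sub = np.arange(events.n)
    emb = embed_waveforms(events.waveforms[sub], seed=seed)
    _, clusters = cluster_events(emb, events.waveforms[sub], min_cluster_size)
    # map subsample-local member indices back to the full event set
    clusters = {
        cid: replace(c, members=sub[c.members]) for cid, c in clusters.items()
    }
    result = match_templates(events, clusters)
    return merge_similar_clusters(result)


def match_event_times(
    estimated: np.ndarray, truth: np.ndarray, tol: float = 0.0015
) -> np.ndarray:
    """Greedy one-to-one matching of estimated to true event times.

    Returns, for each true time, the index of the matched estimate or -1.
    Used to score sorter output against the generator ledger.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(estimated.size, dtype=bool)
    out = np.full(truth.size, -1, dtype=int)
    for i, t in enumerate(truth):
        j = np.searchsorted(estimated, t)
        best, best_dt = -1, tol
        for cand in (j - 1, j):
            if 0 <= cand < estimated.size and not used[cand]:
                dt = abs(estimated[cand] - t)
                if dt <= best_dt:
                    best, best_dt = cand, dt
        if best >= 0:
            out[i] = best
            used[best] = True
    return out
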