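"""Scoring of analysis output against generator ground truth."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .spikesort import SortResult, match_event_times
from .synth import EphysEpisode

__all__ = ["score_sort"]


def score_sort(result: SortResult, episode: EphysEpisode, tol: float = 0.0015) -> dict:
    """Score a sort against the episode's spike ledger.

    Matches detected events to true spike times (greedy, within ``tol``),
    takes each true unit's majority cluster, and reports:

    - ``accuracy``: fraction of true spikes assigned to their unit's
      majority cluster;
    - ``wrong_unit``: fraction of true spikes assigned to a *different*
      unit's majority cluster (merge errors);
    - ``ari``: adjusted Rand index between true unit labels and cluster
      assignments over the matched events;
    - ``n_units``: accepted cluster count.
    """
    est_times = result.events.times
    true_lab = np.full(result.events.n, -1)
    majority: dict[str, int] = {}
    per_unit_assigned: dict[str, np.ndarray] = {}
    for ui, uid in enumerate(episode.spikes):
        tt = np.sort(episode.spikes[uid])
        m = match_event_times(est_times, tt, tol=tol)
        true_lab[m[m >= 0]] = ui
        assigned = result.assignments[m[m >= 0]]
        per_unit_assigned[uid] = assigned
        vals, counts = np.unique(assigned[assigned >= 0], return_counts=True)
        majority[uid] = int(vals[np.argmax(counts)]) if vals.size else -9

    correct = wrong = total = 0
    for uid, assigned in per_unit_assigned.items():
        total += len(episode.spikes[uid])
        correct += int(np.sum(assigned == majority[uid]))
        others = {m for u, m in majority.items() if u != uid}
        wrong += int(np.sum(np.isin(assigned, list(others))))
    ok = true_lab >= 0
    return {
        "accuracy": correct / total if total else 0.0,
        "wrong_unit": wrong / total if total else 0.0,
        "ari": float(adjusted_rand_score(true_lab[ok], result.assignments[ok])),
        "n_units": len(result.unit_ids()),
    }
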