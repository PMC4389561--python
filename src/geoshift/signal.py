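"""Phylogenetic clustering of tip states: parsimony score, association
index, maximum exclusive single-state clade, and a tip-permutation null.

These are the tip-significance statistics of the BaTS family, computed on
a single fixed tree with the tip states permuted uniformly to build the
null distribution:

* **PS** — minimum number of state changes on the tree (Hartigan's
  small-parsimony algorithm, exact on multifurcating trees; equals the
  Fitch count on binary trees).  Lower = more clustered.
* **AI** — association index: sum over internal nodes of
  ``(1 - f) / 2**(n - 1)`` with ``n`` the node's descendant tip count and
  ``f`` the frequency of its most common tip state.  Lower = more
  clustered.
* **MC** — per state, the tip count of the largest clade whose tips all
  carry that state.  Higher = more clustered.

p-values use the add-one estimator ``(1 + #{null at least as clustered})
/ (1 + n_reps)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Chronogram

__all__ = ["ClusteringStats", "parsimony_score", "association_index",
           "max_state_clade", "permutation_test"]


def _states_array(tree: Chronogram, tip_states: pd.Series) \
        -> tuple[np.ndarray, list]:
    ts = pd.Series(tip_states).reindex(tree.tip_labels)
    if ts.isna().any():
        raise ValueError("every tip needs a state")
    names = sorted(ts.unique(), key=str)
    lookup = {s: i for i, s in enumerate(names)}
    return np.array([lookup[s] for s in ts], dtype=np.int64), names


def _parsimony_from_idx(tree: Chronogram, idx: np.ndarray, k: int) -> int:
    # Hartigan: at each internal node keep the states receiving the
    # maximum number of child votes; changes += (#children - max votes)
    sets = np.zeros((tree.n_nodes, k), dtype=bool)
    sets[np.arange(tree.n_tips), idx] = True
    changes = 0
    for nd in tree.postorder:
        if nd < tree.n_tips:
            continue
        votes = sets[tree.children[nd]].sum(axis=0)
        m = votes.max()
        sets[nd] = votes == m
        changes += len(tree.children[nd]) - int(m)
    return changes


def parsimony_score(tree: Chronogram, tip_states: pd.Series) -> int:
    """Minimum number of state changes (small parsimony, exact)."""
    idx, names = _states_array(tree, tip_states)
    return _parsimony_from_idx(tree, idx, len(names))


def _ai_from_idx(tree: Chronogram, idx: np.ndarray, k: int,
                 tip_counts: np.ndarray) -> float:
    # tip_counts[nd, s] accumulated postorder; AI summed over internals
    ai = 0.0
    for nd in tree.postorder:
        if nd < tree.n_tips:
            tip_counts[nd] = 0
            tip_counts[nd, idx[nd]] = 1
        else:
            tip_counts[nd] = tip_counts[tree.children[nd]].sum(axis=0)
            n = tip_counts[nd].sum()
            f = tip_counts[nd].max() / n
            ai += (1.0 - f) / 2.0 ** (n - 1.0)
    return ai


def association_index(tree: Chronogram, tip_states: pd.Series) -> float:
    """Association index; 0 when every tip shares one state."""
    idx, names = _states_array(tree, tip_states)
    buf = np.zeros((tree.n_nodes, len(names)), dtype=np.float64)
    return _ai_from_idx(tree, idx, len(names), buf)


def _mc_from_idx(tree: Chronogram, idx: np.ndarray, k: int,
                 tip_counts: np.ndarray) -> np.ndarray:
    """Largest exclusive single-state clade size per state (tips are
    clades of size 1)."""
    mc = np.zeros(k, dtype=np.int64)
    for nd in tree.postorder:
        if nd < tree.n_tips:
            tip_counts[nd] = 0
            tip_counts[nd, idx[nd]] = 1
        else:
            tip_counts[nd] = tip_counts[tree.children[nd]].sum(axis=0)
        total = tip_counts[nd].sum()
        for s in range(k):
            if tip_counts[nd, s] == total and total > mc[s]:
                mc[s] = total
    return mc


def max_state_clade(tree: Chronogram, tip_states: pd.Series, state) -> int:
    """Tip count of the largest clade whose tips all carry ``state``."""
    idx, names = _states_array(tree, tip_states)
    if state not in names:
        raise ValueError(f"state {state!r} not observed at any tip")
    buf = np.zeros((tree.n_nodes, len(names)), dtype=np.float64)
    mc = _mc_from_idx(tree, idx, len(names), buf)
    return int(mc[names.index(state)])


@dataclass
class ClusteringStats:
    """Observed statistics, permutation nulls, bands and p-values."""

    observed: dict
    null_mean: dict
    null_lo95: dict
    null_hi95: dict
    p_values: dict
    n_reps: int
    state_names: list
    null: dict = field(default_factory=dict)   # statistic -> replicate array
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = {k: getattr(self, k) for k in
                   ("observed", "null_mean", "null_lo95", "null_hi95",
                    "p_values", "n_reps", "meta")}
        payload["states"] = [str(s) for s in self.state_names]
        s = json.dumps(payload, indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def permutation_test(tree: Chronogram, tip_states: pd.Series,
                     n_reps: int = 100, seed: int = 0) -> ClusteringStats:
    """Tip-permutation null for PS, AI and per-state MC.

    Tip states are permuted uniformly across tips ``n_reps`` times
    (``n_reps >= 19``).  "At least as clustered" means null <= observed
    for PS and AI, null >= observed for MC.
    """
    if n_reps < 19:
        raise ValueError("n_reps must be >= 19 for a meaningful null")
    idx, names = _states_array(tree, tip_states)
    k = len(names)
    buf = np.zeros((tree.n_nodes, k), dtype=np.float64)
    obs_ps = _parsimony_from_idx(tree, idx, k)
    obs_ai = _ai_from_idx(tree, idx, k, buf)
    obs_mc = _mc_from_idx(tree, idx, k, buf)

    rng = np.random.default_rng(seed)
    null_ps = np.empty(n_reps)
    null_ai = np.empty(n_reps)
    null_mc = np.empty((n_reps, k))
    for r in range(n_reps):
        perm = rng.permutation(idx)
        null_ps[r] = _parsimony_from_idx(tree, perm, k)
        null_ai[r] = _ai_from_idx(tree, perm, k, buf)
        null_mc[r] = _mc_from_idx(tree, perm, k, buf)

    def addone(n_as_clustered: int) -> float:
        return (1 + n_as_clustered) / (1 + n_reps)

    observed = {"PS": int(obs_ps), "AI": float(obs_ai)}
    null = {"PS": null_ps, "AI": null_ai}
    p = {"PS": addone(int((null_ps <= obs_ps).sum())),
         "AI": addone(int((null_ai <= obs_ai).sum()))}
    mean = {"PS": float(null_ps.mean()), "AI": float(null_ai.mean())}
    lo = {"PS": float(np.percentile(null_ps, 2.5)),
          "AI": float(np.percentile(null_ai, 2.5))}
    hi = {"PS": float(np.percentile(null_ps, 97.5)),
          "AI": float(np.percentile(null_ai, 97.5))}
    for s, name in enumerate(names):
        key = f"MC:{name}"
        observed[key] = int(obs_mc[s])
        null[key] = null_mc[:, s]
        p[key] = addone(int((null_mc[:, s] >= obs_mc[s]).sum()))
        mean[key] = float(null_mc[:, s].mean())
        lo[key] = float(np.percentile(null_mc[:, s], 2.5))
        hi[key] = float(np.percentile(null_mc[:, s], 97.5))
    meta = {"seed": seed,
            "formulas": {
                "PS": "Hartigan/Fitch minimum state changes",
                "AI": "sum over internal nodes of (1-f)/2^(n-1)",
                "MC": "largest clade with all tips in the state"},
            "direction": {"PS": "low = clustered", "AI": "low = clustered",
                          "MC": "high = clustered"}}
    return ClusteringStats(observed, mean, lo, hi, p, n_reps, names,
                           null=null, meta=meta)
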