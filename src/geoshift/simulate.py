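"""Synthetic data generation: state-dependent birth–death trees with known
histories, tip subsampling, toy region polygons and contaminated occurrence
tables.

This module produces every input the downstream pipeline consumes, so the
whole analysis can be exercised end-to-end with ground truth in hand: the
simulator records the *true* timed state-transition events on every
surviving branch (:class:`TrueHistory`), and the occurrence generator keeps
row-level ground-truth labels for every injected pathology.

The generating process is the multi-state speciation/extinction (MuSSE)
model: a lineage in state ``i`` speciates at rate ``lambda_i``, goes extinct
at rate ``mu_i`` and jumps to state ``j`` at rate ``q_ij`` (all per lineage
per Myr), simulated exactly with the Gillespie algorithm and pruned to the
reconstructed (extant-only) tree.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry

from .regions import RegionSet
from .trees import Chronogram

__all__ = [
    "SimConfig", "TrueHistory", "ExtinctReplicateError", "ContaminationRates",
    "simulate_musse_tree", "subsample_tips", "make_region_fixtures",
    "generate_occurrences", "substream_seed",
]


def substream_seed(master: int, label: str) -> int:
    """Derive a deterministic per-operation seed (< 2**31) from a master seed."""
    return (int(master) ^ zlib.crc32(label.encode())) % (2 ** 31 - 1)


class ExtinctReplicateError(RuntimeError):
    """The simulated clade died before leaving 2 surviving tips; retry."""


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC rate matrix (uniform over the
    communicating classes' nullspace basis if not unique)."""
    k = q.shape[0]
    if k == 1:
        return np.ones(1)
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class SimConfig:
    """Parameters of the state-dependent birth–death simulation.

    ``lam``/``mu`` are per-state speciation/extinction rates
    (events/lineage/Myr); ``q`` is the k×k transition rate matrix with
    non-negative off-diagonals and rows summing to zero.  Exactly one of
    ``max_time`` (Myr) / ``max_taxa`` may be left unset.
    """

    n_states: int
    lam: np.ndarray
    mu: np.ndarray
    q: np.ndarray
    max_time: float | None = None
    max_taxa: int | None = None
    seed: int = 0
    root_state: int | None = None  # None: draw from stationary distribution

    def __post_init__(self):
        k = int(self.n_states)
        self.lam = np.broadcast_to(np.asarray(self.lam, float), (k,)).copy()
        self.mu = np.broadcast_to(np.asarray(self.mu, float), (k,)).copy()
        q = np.asarray(self.q, float)
        if q.ndim == 0:
            q = np.full((k, k), float(q))
        if q.shape != (k, k):
            raise ValueError(f"q must be {k}x{k}")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0) or not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal transition rates must be finite, >= 0")
        np.fill_diagonal(off, -off.sum(axis=1))
        self.q = off
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValueError("rates must be >= 0")
        if self.max_time is None and self.max_taxa is None:
            raise ValueError("set max_time and/or max_taxa")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.max_taxa is not None and self.max_taxa < 2:
            raise ValueError("max_taxa must be >= 2")
        if self.root_state is not None and not 0 <= self.root_state < k:
            raise ValueError("root_state out of range")


@dataclass
class TrueHistory:
    """Ground-truth character history on a reconstructed tree.

    ``events`` has one row per transition on a surviving branch, with the
    branch identified by its child-node index in the accompanying
    :class:`~geoshift.trees.Chronogram`; ages are Ma before present.
    ``node_states`` gives the true state at every node (tips included).
    """

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["branch", "age", "from_state", "to_state"]))
    node_states: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_events(self) -> int:
        return len(self.events)

    def branch_segments(self, tree: Chronogram, branch: int) \
            -> list[tuple[float, float, int]]:
        """(older age, younger age, state) segments along one branch."""
        top = float(tree.age[tree.parent[branch]])
        bot = float(tree.age[branch])
        ev = self.events[self.events["branch"] == branch]
        ev = ev.sort_values("age", ascending=False)
        segs = []
        state = int(self.node_states[tree.parent[branch]])
        t0 = top
        for _, row in ev.iterrows():
            segs.append((t0, float(row["age"]), state))
            assert int(row["from_state"]) == state, "segment/event mismatch"
            state = int(row["to_state"])
            t0 = float(row["age"])
        segs.append((t0, bot, state))
        return segs

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for _, r in self.events.iterrows():
                fh.write(json.dumps({"branch": int(r["branch"]),
                                     "age": float(r["age"]),
                                     "from": int(r["from_state"]),
                                     "to": int(r["to_state"])}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str, node_states=None) -> "TrueHistory":
        rows = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                rows.append((d["branch"], d["age"], d["from"], d["to"]))
        ev = pd.DataFrame(rows, columns=["branch", "age", "from_state",
                                         "to_state"])
        return cls(ev, np.asarray(node_states if node_states is not None
                                  else [], int))


# ----------------------------------------------------------------------
# Gillespie simulation of the MuSSE process
# ----------------------------------------------------------------------
def simulate_musse_tree(config: SimConfig) \
        -> tuple[Chronogram, TrueHistory, pd.Series]:
    """Simulate a reconstructed (extant-only) tree under the MuSSE process.

    Returns the pruned ultrametric tree (crown subtree of the survivors,
    ages in Ma before present), the :class:`TrueHistory` of transitions on
    surviving branches, and tip states as a pandas Series indexed by tip
    label.

    Raises
    ------
    ExtinctReplicateError
        If fewer than 2 lineages survive to the stopping time.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_states
    lam, mu, q = config.lam, config.mu, config.q
    qout = -np.diag(q)
    per_state_rate = lam + mu + qout

    if config.root_state is not None:
        root_state = int(config.root_state)
    else:
        root_state = int(rng.choice(k, p=stationary_distribution(q)))

    # per-lineage records
    parent_lin = [-1]
    t_birth = [0.0]
    t_end = [np.inf]
    state0 = [root_state]          # state at birth
    cur_state = [root_state]
    ev_time: list[list[float]] = [[]]
    ev_from: list[list[int]] = [[]]
    ev_to: list[list[int]] = [[]]
    kids: list[list[int]] = [[]]
    alive_flag = [True]

    active_by_state: list[set[int]] = [set() for _ in range(k)]
    active_by_state[root_state].add(0)
    n_active = 1
    t = 0.0
    t_stop = config.max_time if config.max_time is not None else np.inf

    while n_active:
        counts = np.array([len(s) for s in active_by_state], float)
        total = float(counts @ per_state_rate)
        if total <= 0:
            t = t_stop if np.isfinite(t_stop) else t
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_stop:
            t = t_stop
            break
        t = t_next
        # pick state class, then event type
        s = int(rng.choice(k, p=counts * per_state_rate / total))
        lin = int(rng.choice(sorted(active_by_state[s])))
        u = rng.uniform(0.0, per_state_rate[s])
        if u < lam[s]:                                # speciation
            t_end[lin] = t
            active_by_state[s].discard(lin)
            for _ in range(2):
                idx = len(parent_lin)
                parent_lin.append(lin)
                t_birth.append(t)
                t_end.append(np.inf)
                state0.append(s)
                cur_state.append(s)
                ev_time.append([])
                ev_from.append([])
                ev_to.append([])
                kids.append([])
                alive_flag.append(True)
                kids[lin].append(idx)
                active_by_state[s].add(idx)
            n_active += 1
            if config.max_taxa is not None and n_active >= config.max_taxa:
                t_stop = t
                break
        elif u < lam[s] + mu[s]:                      # extinction
            t_end[lin] = t
            alive_flag[lin] = False
            active_by_state[s].discard(lin)
            n_active -= 1
        else:                                         # state transition
            w = q[s].copy()
            w[s] = 0.0
            j = int(rng.choice(k, p=w / w.sum()))
            ev_time[lin].append(t)
            ev_from[lin].append(s)
            ev_to[lin].append(j)
            cur_state[lin] = j
            active_by_state[s].discard(lin)
            active_by_state[j].add(lin)

    present = t
    extant = [i for i in range(len(parent_lin))
              if alive_flag[i] and not np.isfinite(t_end[i])]
    for i in extant:
        t_end[i] = present
    if len(extant) < 2:
        raise ExtinctReplicateError(
            f"only {len(extant)} lineage(s) survived; retry with a new seed")

    # mark lineages with extant descendants
    survives = [False] * len(parent_lin)
    for i in extant:
        j = i
        while j >= 0 and not survives[j]:
            survives[j] = True
            j = parent_lin[j]

    # crown root: first lineage (from the origin) with 2 surviving children,
    # or an extant lineage if only via chains (cannot happen with >=2 tips)
    node = 0
    while True:
        sk = [c for c in kids[node] if survives[c]]
        if len(sk) != 1:
            break
        node = sk[0]
    crown = node

    # Build merged branches: walk from crown; each branch is a chain of
    # lineages ending at a tip or a bifurcation.  Events on the stem above
    # the crown are discarded; events on merged chains are concatenated.
    tips: list[int] = []          # final node ids for tips assigned later
    records = []  # (chain_start_lineage, parent_record_index)

    def chain_end(start: int) -> tuple[int, list[int]]:
        """Follow single-surviving-child chains; return (terminal, chain)."""
        chain = [start]
        cur = start
        while True:
            sk = [c for c in kids[cur] if survives[c]]
            if len(sk) == 1:
                cur = sk[0]
                chain.append(cur)
            else:
                return cur, chain

    # BFS over merged-branch structure
    branch_defs = []  # (chain lineages, parent branch id or -1)
    stack = [(crown, -1)]
    while stack:
        start, par = stack.pop()
        term, chain = chain_end(start)
        bid = len(branch_defs)
        branch_defs.append((chain, par, term))
        sk = [c for c in kids[term] if survives[c]]
        for c in sk:
            stack.append((c, bid))

    n_branch = len(branch_defs)
    is_tip = [len([c for c in kids[term] if survives[c]]) == 0
              for (_, _, term) in branch_defs]
    n_tips = sum(is_tip)
    # node ids: tips first, then internals, root last
    tip_ids = iter(range(n_tips))
    internal_ids = iter(range(n_tips, n_branch))
    node_of_branch = [0] * n_branch
    # root (branch 0) must get the *last* internal id -> assign internals to
    # non-root branches first
    internal_branches = [b for b in range(n_branch) if not is_tip[b]]
    # ensure branch 0 (crown) receives the highest id
    internal_branches_sorted = [b for b in internal_branches if b != 0] + [0]
    for b, nid in zip(internal_branches_sorted,
                      range(n_tips, n_branch)):
        node_of_branch[b] = nid
    for b in range(n_branch):
        if is_tip[b]:
            node_of_branch[b] = next(tip_ids)

    parent = np.full(n_branch, -1, dtype=np.int64)
    blen = np.zeros(n_branch)
    node_state = np.zeros(n_branch, dtype=np.int64)
    ev_rows = []
    labels = [""] * n_tips
    for b, (chain, par, term) in enumerate(branch_defs):
        nid = node_of_branch[b]
        start = chain[0]
        blen[nid] = t_end[term] - t_birth[start]
        if par >= 0:
            parent[nid] = node_of_branch[par]
        node_state[nid] = cur_state[term]
        if b != 0:  # stem events above the crown root are discarded
            for lin in chain:
                for et, ef, eto in zip(ev_time[lin], ev_from[lin], ev_to[lin]):
                    ev_rows.append((nid, present - et, ef, eto))
        if is_tip[b]:
            labels[nid] = f"t{nid + 1}"
    blen[node_of_branch[0]] = 0.0   # crown root carries no stem edge

    tree = Chronogram(parent, blen, labels)
    events = pd.DataFrame(ev_rows, columns=["branch", "age", "from_state",
                                            "to_state"])
    events = events.sort_values(["branch", "age"],
                                ascending=[True, False]).reset_index(drop=True)
    history = TrueHistory(events, node_state)
    tip_states = pd.Series(node_state[: n_tips], index=labels, name="state")
    return tree, history, tip_states


def subsample_tips(tree: Chronogram, states: pd.Series,
                   rho: np.ndarray | dict, seed: int = 0) \
        -> tuple[Chronogram, pd.Series, pd.DataFrame]:
    """Retain each tip independently with state-specific probability.

    Emulates incomplete taxonomic sampling: tip ``i`` in state ``s`` is kept
    with probability ``rho[s]``.  Returns the pruned tree, the retained tip
    states, and a per-state table of (total, kept, realized fraction).
    """
    states = states.reindex(tree.tip_labels)
    if states.isna().any():
        raise ValueError("every tip needs a state")
    uniq = sorted(set(int(s) for s in states))
    if isinstance(rho, dict):
        rho_of = {int(s): float(rho[s]) for s in uniq}
    else:
        rho = np.atleast_1d(np.asarray(rho, float))
        rho_of = {s: float(rho[s] if rho.size > 1 else rho[0]) for s in uniq}
    for s, r in rho_of.items():
        if not 0 < r <= 1:
            raise ValueError(f"rho for state {s} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep_mask = np.array([rng.random() < rho_of[int(states[lab])]
                          for lab in tree.tip_labels])
    kept = [lab for lab, m in zip(tree.tip_labels, keep_mask) if m]
    rows = []
    for s in uniq:
        tot = int((states == s).sum())
        nk = int(sum(1 for lab in kept if states[lab] == s))
        rows.append((s, tot, nk, nk / tot if tot else np.nan))
    realized = pd.DataFrame(rows, columns=["state", "n_total", "n_kept",
                                           "fraction"])
    if len(kept) < 2:
        raise ValueError(
            f"subsampling left {len(kept)} tip(s); cannot build a tree")
    if len(kept) == tree.n_tips:
        return tree, states, realized
    pruned = tree.prune_to(kept)
    return pruned, states.loc[pruned.tip_labels], realized


# ----------------------------------------------------------------------
# Toy geography
# ----------------------------------------------------------------------
def make_region_fixtures() -> RegionSet:
    """Four disjoint lon/lat rectangles standing in for the study regions.

    Deterministic; precedence order is the listing order below.
    """
    box = shapely.geometry.box
    regions = {
        "AmericanTropics": box(-80.0, -15.0, -50.0, 15.0),
        "AfricanTropics": box(10.0, -15.0, 40.0, 15.0),
        "AsianTropics": box(95.0, -10.0, 125.0, 20.0),
        "NonTropical": box(-30.0, 35.0, 30.0, 60.0),
    }
    return RegionSet(regions)


@dataclass
class ContaminationRates:
    """Per-row probabilities of injecting each occurrence-table pathology.

    Every rate is a per-clean-point probability of *adding* one pathological
    row (except ``stray``, which relocates a clean point into a wrong
    region, keeping the row otherwise valid).
    """

    duplicate: float = 0.0
    zero_coord: float = 0.0
    lat_eq_lon: float = 0.0
    missing_name: float = 0.0
    non_numeric: float = 0.0
    flagged: float = 0.0
    stray: float = 0.0
    stray_region: str | None = None

    def __post_init__(self):
        for f in ("duplicate", "zero_coord", "lat_eq_lon", "missing_name",
                  "non_numeric", "flagged", "stray"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{f} rate must be in [0, 1]")


def _uniform_in(rng: np.random.Generator, poly, n: int) \
        -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        m = max(16, 2 * (n - filled))
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(poly, x, y)
        take = min(n - filled, int(ok.sum()))
        xs[filled:filled + take] = x[ok][:take]
        ys[filled:filled + take] = y[ok][:take]
        filled += take
    return xs, ys


def generate_occurrences(species_ranges: dict, rates: ContaminationRates,
                         seed: int = 0, regions: RegionSet | None = None) \
        -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw occurrence table with controlled contamination.

    ``species_ranges`` maps species name -> (home region name, n clean
    points).  Returns ``(table, truth)`` with aligned row indices: ``table``
    has the raw CSV columns (species, decimalLongitude, decimalLatitude,
    flag), ``truth`` records each row's pathology ('clean', 'stray',
    'duplicate', ...) and true home region.  Pathological rows are appended
    after the clean rows so a cleaner pass can be checked row-for-row.
    """
    if regions is None:
        regions = make_region_fixtures()
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    truth: list[tuple] = []

    def add(species, lon, lat, flag, pathology, region):
        rows.append((species, lon, lat, flag))
        truth.append((pathology, region))

    clean_idx_by_species: dict[str, list[int]] = {}
    for sp, (region, n) in species_ranges.items():
        if region not in regions.regions:
            raise KeyError(f"unknown region {region!r}")
        if n < 0:
            raise ValueError("n_points must be >= 0")
        other = [r for r in regions.names if r != region]
        xs, ys = _uniform_in(rng, regions.regions[region], n)
        stray_mask = rng.random(n) < rates.stray
        for i in range(n):
            if stray_mask[i]:
                tgt = rates.stray_region or str(rng.choice(other))
                sx, sy = _uniform_in(rng, regions.regions[tgt], 1)
                add(sp, float(sx[0]), float(sy[0]), "", "stray", region)
            else:
                clean_idx_by_species.setdefault(sp, []).append(len(rows))
                add(sp, float(xs[i]), float(ys[i]), "", "clean", region)

    # appended pathological rows, one block per pathology, deterministic order
    for sp, (region, n) in species_ranges.items():
        if n == 0:
            continue
        poly = regions.regions[region]
        pool = clean_idx_by_species.get(sp, [])

        def rand_point():
            x, y = _uniform_in(rng, poly, 1)
            return float(x[0]), float(y[0])

        for _ in range(rng.binomial(n, rates.duplicate)):
            if not pool:
                break
            src = rows[int(rng.choice(pool))]
            add(src[0], src[1], src[2], src[3], "duplicate", region)
        for _ in range(rng.binomial(n, rates.zero_coord)):
            x, y = rand_point()
            if rng.random() < 0.5:
                add(sp, 0.0, y, "", "zero_coord", region)
            else:
                add(sp, x, 0.0, "", "zero_coord", region)
        for _ in range(rng.binomial(n, rates.lat_eq_lon)):
            v = float(rng.uniform(-60, 60))
            add(sp, v, v, "", "lat_eq_lon", region)
        for _ in range(rng.binomial(n, rates.missing_name)):
            x, y = rand_point()
            add("", x, y, "", "missing_name", region)
        for _ in range(rng.binomial(n, rates.non_numeric)):
            x, y = rand_point()
            add(sp, f"{abs(x):.2f}W", f"{y:.2f}", "", "non_numeric", region)
        for _ in range(rng.binomial(n, rates.flagged)):
            x, y = rand_point()
            add(sp, x, y, "geo_issue", "flagged", region)

    table = pd.DataFrame(rows, columns=["species", "decimalLongitude",
                                        "decimalLatitude", "flag"])
    truth_df = pd.DataFrame(truth, columns=["pathology", "true_region"])
    return table, truth_df
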