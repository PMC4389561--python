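"""Continuous-time Markov (Mk) models of region evolution on a chronogram:
likelihood, ML fitting, stochastic character mapping, and binned
range-shift-rate statistics.

The Mk model is parameterized by a k×k instantaneous rate matrix Q
(off-diagonals >= 0, rows sum to 0).  The likelihood is computed by
Felsenstein pruning with per-branch transition probabilities exp(Q t).
Stochastic maps are drawn by sampling node states from their joint
conditional distribution (root to tips) and then sampling each branch's
path conditional on its endpoint states by uniformization, i.e. by
embedding the chain in a Poisson process with dominating rate
``max_i |Q_ii|``.

The headline statistic is the *relative* number of range shifts through
time: mapped transition counts per time bin divided by the number of
lineages available in the bin, averaged over replicate maps with empirical
95% bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .simulate import TrueHistory, stationary_distribution
from .trees import Chronogram

__all__ = [
    "MkModel", "MkResults", "StochasticHistory", "BinnedShiftRates",
    "mk_loglik", "fit_mk", "sample_stochastic_map", "count_transitions",
    "lineages_in_bin", "relative_shift_rates", "make_bins",
]

RATE_BOUNDS = (1e-8, 100.0)   # events/Myr, ML search box


class StochasticHistory(TrueHistory):
    """One sampled character history: timed transition events per branch
    plus sampled node states (same layout as the simulator's ground
    truth)."""


# ----------------------------------------------------------------------
# rate-matrix parameterizations
# ----------------------------------------------------------------------
def _n_free(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model class {model!r}")


def build_q(rates: np.ndarray, model: str, k: int) -> np.ndarray:
    """Assemble Q from the free off-diagonal rates of a model class."""
    rates = np.asarray(rates, float)
    q = np.zeros((k, k))
    if model == "ER":
        q[:] = rates[0]
    elif model == "SYM":
        it = iter(rates)
        for i in range(k):
            for j in range(i + 1, k):
                q[i, j] = q[j, i] = next(it)
    elif model == "ARD":
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    q[i, j] = next(it)
    else:
        raise ValueError(f"unknown model class {model!r}")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_matrices(q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t, via eigendecomposition with expm fallback."""
    k = q.shape[0]
    ts = np.asarray(ts, float)
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) < 1e8:
            e = np.exp(np.multiply.outer(ts, w))           # (n, k)
            p = np.einsum("ij,nj,jl->nil", v, e, vinv).real
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=2, keepdims=True)
            return p
    except np.linalg.LinAlgError:
        pass
    return np.stack([scipy.linalg.expm(q * t) for t in ts])


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def _encode_states(tree: Chronogram, tip_states: pd.Series,
                   state_names: list | None = None):
    ts = pd.Series(tip_states).reindex(tree.tip_labels)
    if ts.isna().any():
        missing = [l for l in tree.tip_labels if pd.isna(ts[l])][:5]
        raise ValueError(f"tips without states, e.g. {missing}")
    if state_names is None:
        state_names = sorted(ts.unique(), key=str)
    lookup = {s: i for i, s in enumerate(state_names)}
    try:
        idx = np.array([lookup[s] for s in ts], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"unknown tip state {e.args[0]!r}") from None
    return idx, list(state_names)


def _pruning_partials(tree: Chronogram, state_idx: np.ndarray,
                      q: np.ndarray):
    """Downward partial likelihoods D and per-branch transition matrices.

    Returns (D, logscale, P) where ``D[n]`` is the scaled partial
    likelihood vector at node n, ``logscale`` the accumulated log of the
    scaling factors, and ``P[n]`` = exp(Q * blen[n]) for the branch above n.
    """
    k = q.shape[0]
    p = transition_matrices(q, tree.blen)
    d = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    for nd in tree.postorder:
        if nd < tree.n_tips:
            d[nd, state_idx[nd]] = 1.0
        else:
            acc = np.ones(k)
            for c in tree.children[nd]:
                acc = acc * (p[c] @ d[c])
            mx = acc.max()
            if mx <= 0:
                raise FloatingPointError(
                    f"zero partial likelihood at node {nd}")
            d[nd] = acc / mx
            logscale += np.log(mx)
    return d, logscale, p


def _root_weights(root_prior, d_root: np.ndarray, q: np.ndarray) \
        -> np.ndarray:
    k = q.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return stationary_distribution(q)
        if root_prior == "uniform":
            return np.full(k, 1.0 / k)
        if root_prior == "fitzjohn":
            s = d_root.sum()
            return d_root / s if s > 0 else np.full(k, 1.0 / k)
        raise ValueError(f"unknown root prior {root_prior!r}")
    w = np.asarray(root_prior, float)
    if w.shape != (k,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("root prior must be a length-k vector summing to 1")
    return w


def mk_loglik(tree: Chronogram, tip_states: pd.Series, q: np.ndarray,
              root_prior="stationary", state_names: list | None = None) \
        -> float:
    """Felsenstein pruning log-likelihood of tip states under Q."""
    tree.assert_ultrametric()
    idx, names = _encode_states(tree, tip_states, state_names)
    q = np.asarray(q, float)
    if q.shape != (len(names), len(names)):
        raise ValueError(f"Q must be {len(names)}x{len(names)} for the "
                         f"observed state set {names}")
    d, logscale, _ = _pruning_partials(tree, idx, q)
    w = _root_weights(root_prior, d[tree.root], q)
    lik = float(w @ d[tree.root])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + logscale


def node_marginals(tree: Chronogram, tip_states: pd.Series, q: np.ndarray,
                   root_prior="stationary",
                   state_names: list | None = None) -> np.ndarray:
    """Marginal conditional state probabilities at every node (up-down
    algorithm); rows sum to 1."""
    idx, names = _encode_states(tree, tip_states, state_names)
    q = np.asarray(q, float)
    k = q.shape[0]
    d, _, p = _pruning_partials(tree, idx, q)
    f = np.zeros((tree.n_nodes, k))          # outside partials
    f[tree.root] = _root_weights(root_prior, d[tree.root], q)
    for nd in tree.postorder[::-1]:          # preorder
        if nd < tree.n_tips:
            continue
        msgs = {c: p[c] @ d[c] for c in tree.children[nd]}
        for c in tree.children[nd]:
            excl = f[nd].copy()
            for s in tree.children[nd]:
                if s != c:
                    excl *= msgs[s]
            f[c] = excl @ p[c]
    marg = f * d
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------
class MkModel:
    """Mk model of a discrete region character on a dated tree.

    Parameters
    ----------
    tree, tip_states
        Chronogram and one observed state per tip.
    model
        Rate-matrix class: ``"ER"`` (equal rates), ``"SYM"`` or ``"ARD"``
        (all rates different; the default, since directional immigration
        vs emigration is usually the quantity of interest).
    root_prior
        ``"stationary"`` (default), ``"uniform"``, ``"fitzjohn"``, or an
        explicit probability vector.
    """

    def __init__(self, tree: Chronogram, tip_states: pd.Series,
                 model: str = "ARD", root_prior="stationary",
                 state_names: list | None = None):
        tree.assert_ultrametric()
        self.tree = tree
        self.model = model
        self.root_prior = root_prior
        self.state_idx, self.state_names = _encode_states(
            tree, tip_states, state_names)
        self.k = len(self.state_names)
        self.tip_states = pd.Series(tip_states).reindex(tree.tip_labels)

    def loglike(self, rates_or_q) -> float:
        q = np.asarray(rates_or_q, float)
        if q.ndim == 1:
            q = build_q(q, self.model, self.k)
        d, logscale, _ = _pruning_partials(self.tree, self.state_idx, q)
        w = _root_weights(self.root_prior, d[self.tree.root], q)
        lik = float(w @ d[self.tree.root])
        return np.log(lik) + logscale if lik > 0 else -np.inf

    def fit(self, starts: int = 3) -> "MkResults":
        """Maximize the likelihood over the free rates (L-BFGS-B on log
        rates, bounds [1e-8, 100]/Myr, deterministic multi-start)."""
        if len(np.unique(self.state_idx)) < 2:
            raise ValueError("character invariant; rates unidentifiable")
        nf = _n_free(self.model, self.k)
        # heuristic rate scale: tip-sequence state changes / total length
        changes = max(1, int(np.sum(self.state_idx[:-1]
                                    != self.state_idx[1:])))
        base = changes / max(self.tree.total_length, 1e-9)
        lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
        scales = [0.2, 1.0, 5.0, 25.0, 0.04][:max(starts, 1)]
        best = None
        trace = []
        for s in scales:
            x0 = np.full(nf, np.clip(np.log(base * s), lo, hi))
            res = scipy.optimize.minimize(
                lambda x: -self.loglike(np.exp(x)), x0,
                method="L-BFGS-B", bounds=[(lo, hi)] * nf)
            trace.append({"start_scale": s, "llf": -res.fun,
                          "converged": bool(res.success)})
            if best is None or -res.fun > best[0]:
                best = (-res.fun, np.exp(res.x), res)
        llf, rates, res = best
        return MkResults(self, rates=rates, llf=llf,
                         converged=bool(res.success), trace=trace)


class MkResults:
    """Fitted Mk model: rate estimates, log-likelihood, mapping methods."""

    def __init__(self, model: MkModel, rates: np.ndarray, llf: float,
                 converged: bool = True, trace: list | None = None):
        self.model = model
        self.rates = np.asarray(rates, float)
        self.q = build_q(self.rates, model.model, model.k)
        self.llf = float(llf)
        self.converged = converged
        self.trace = trace or []

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.model.state_names,
                            columns=self.model.state_names)

    def summary(self) -> str:
        lines = [
            "Mk model of region evolution",
            "=" * 44,
            f"model class:     {self.model.model}",
            f"states:          {self.model.state_names}",
            f"tips:            {self.model.tree.n_tips}",
            f"root prior:      {self.model.root_prior}",
            f"log-likelihood:  {self.llf:.6f}",
            f"converged:       {self.converged}",
            "rate matrix Q (events/lineage/Myr):",
            self.params.round(6).to_string(),
        ]
        return "\n".join(lines)

    def sample_map(self, seed: int = 0) -> StochasticHistory:
        return sample_stochastic_map(
            self.model.tree, self.model.tip_states, self.q,
            root_prior=self.model.root_prior, seed=seed,
            state_names=self.model.state_names)

    def sample_maps(self, n: int, seed: int = 0) -> list[StochasticHistory]:
        return [self.sample_map(seed=seed + i) for i in range(n)]

    def relative_shift_rates(self, n_maps: int = 100, bin_width: float = 5.0,
                             seed: int = 0, denominator: str = "branches") \
            -> "BinnedShiftRates":
        return relative_shift_rates(
            self.model.tree, self.model.tip_states, self.q,
            root_prior=self.model.root_prior, n_maps=n_maps,
            bin_width=bin_width, seed=seed, denominator=denominator,
            state_names=self.model.state_names)


def fit_mk(tree: Chronogram, tip_states: pd.Series, model: str = "ARD",
           root_prior="stationary", starts: int = 3) -> MkResults:
    """Convenience wrapper: build an :class:`MkModel` and fit it."""
    return MkModel(tree, tip_states, model=model,
                   root_prior=root_prior).fit(starts=starts)


# ----------------------------------------------------------------------
# stochastic character mapping
# ----------------------------------------------------------------------
class _Mapper:
    """Precomputed quantities for drawing many maps from one model."""

    def __init__(self, tree: Chronogram, tip_states: pd.Series,
                 q: np.ndarray, root_prior="stationary",
                 state_names: list | None = None):
        tree.assert_ultrametric()
        self.tree = tree
        self.q = np.asarray(q, float)
        self.k = self.q.shape[0]
        idx, self.state_names = _encode_states(tree, tip_states, state_names)
        if len(self.state_names) > self.k:
            raise ValueError("more observed states than rows of Q")
        self.state_idx = idx
        self.d, _, self.p = _pruning_partials(tree, idx, self.q)
        self.w_root = _root_weights(root_prior, self.d[tree.root], self.q)
        # uniformization: dominating rate and jump matrix
        self.lam_dom = float(np.max(-np.diag(self.q)))
        if self.lam_dom > 0:
            self.r = np.eye(self.k) + self.q / self.lam_dom
        else:
            self.r = np.eye(self.k)
        self.rpow = [np.eye(self.k), self.r.copy()]

    def _rpow(self, n: int) -> np.ndarray:
        while len(self.rpow) <= n:
            self.rpow.append(self.rpow[-1] @ self.r)
        return self.rpow[n]

    def _sample_n_jumps(self, rng, i, j, t) -> int:
        """Number of uniformized jumps conditional on endpoints (i, j)."""
        lam_t = self.lam_dom * t
        pij = float(self.p_branch[i, j])
        u = rng.random() * pij
        n = 0
        log_pois = -lam_t
        acc = 0.0
        while True:
            term = np.exp(log_pois) * self._rpow(n)[i, j]
            acc += term
            if acc >= u or n > 100000:
                return n
            n += 1
            log_pois += np.log(lam_t) - np.log(n)

    def sample(self, seed: int) -> StochasticHistory:
        rng = np.random.default_rng(seed)
        tree = self.tree
        node_state = np.full(tree.n_nodes, -1, dtype=np.int64)
        node_state[: tree.n_tips] = self.state_idx
        # sample node states root -> tips from the joint conditional
        wr = self.w_root * self.d[tree.root]
        wr = wr / wr.sum()
        node_state[tree.root] = rng.choice(self.k, p=wr)
        for nd in tree.postorder[::-1]:
            for c in tree.children[nd]:
                if c < tree.n_tips:
                    continue
                w = self.p[c][node_state[nd]] * self.d[c]
                s = w.sum()
                if s <= 0:
                    raise FloatingPointError(
                        f"zero-probability endpoint pair on branch {c}")
                node_state[c] = rng.choice(self.k, p=w / s)
        # sample per-branch paths conditional on endpoints
        rows = []
        for c in range(tree.n_nodes):
            par = tree.parent[c]
            if par < 0:
                continue
            t = float(tree.blen[c])
            i, j = int(node_state[par]), int(node_state[c])
            if t <= 0:
                if i != j:
                    raise FloatingPointError(
                        f"state change across zero-length branch {c}")
                continue
            self.p_branch = self.p[c]
            if self.p_branch[i, j] <= 0:
                raise FloatingPointError(
                    f"zero-probability endpoint pair on branch {c}")
            if self.lam_dom == 0:
                continue
            n = self._sample_n_jumps(rng, i, j, t)
            if n == 0:
                continue
            times = np.sort(rng.uniform(0.0, t, n))
            states = np.empty(n + 1, dtype=np.int64)
            states[0] = i
            for m in range(1, n):
                w = self.r[states[m - 1]] * self._rpow(n - m)[:, j]
                states[m] = rng.choice(self.k, p=w / w.sum())
            states[n] = j
            # check last jump consistency: R[states[n-1], j] must be > 0
            age_top = float(tree.age[par])
            prev = states[0]
            for m in range(1, n + 1):
                if states[m] != prev:
                    rows.append((c, age_top - times[m - 1], int(prev),
                                 int(states[m])))
                    prev = states[m]
        events = pd.DataFrame(rows, columns=["branch", "age", "from_state",
                                             "to_state"])
        events = events.sort_values(["branch", "age"],
                                    ascending=[True, False]
                                    ).reset_index(drop=True)
        return StochasticHistory(events, node_state)


def sample_stochastic_map(tree: Chronogram, tip_states: pd.Series,
                          q: np.ndarray, root_prior="stationary",
                          seed: int = 0, state_names: list | None = None) \
        -> StochasticHistory:
    """Draw one stochastic character map conditional on the tip states."""
    return _Mapper(tree, tip_states, q, root_prior, state_names).sample(seed)


# ----------------------------------------------------------------------
# binned transition statistics
# ----------------------------------------------------------------------
def make_bins(root_age: float, width: float = 5.0) -> np.ndarray:
    """Bin edges anchored at the present: [0, w, 2w, ...] covering the
    root age (the oldest bin may extend past it)."""
    n = int(np.ceil(root_age / width)) if root_age > 0 else 1
    return np.arange(n + 1, dtype=float) * width


def _direction_mask(events: pd.DataFrame, direction) -> np.ndarray:
    if direction == "all":
        return np.ones(len(events), dtype=bool)
    frm, to = direction
    m = np.ones(len(events), dtype=bool)
    if frm != "any":
        m &= (events["from_state"] == frm).to_numpy()
    if to != "any":
        m &= (events["to_state"] == to).to_numpy()
    return m


def count_transitions(history: TrueHistory, bins: np.ndarray,
                      direction="all") -> np.ndarray:
    """Tally mapped events into age bins for one direction.

    ``direction`` is ``"all"``, a ``(from, to)`` pair of state indices, or
    an aggregate with ``"any"`` on one side (e.g. ``(1, "any")`` counts all
    emigration out of state 1).  Raises if any event age falls outside the
    bins (inconsistent age axis).
    """
    bins = np.asarray(bins, float)
    ev = history.events
    ages = ev["age"].to_numpy(float)
    if len(ages) and (ages.min() < bins[0] or ages.max() >= bins[-1]):
        raise ValueError("event age outside the bin range; the bins must "
                         "cover the tree's age span")
    sel = ages[_direction_mask(ev, direction)]
    counts, _ = np.histogram(sel, bins=bins)
    return counts


def lineages_in_bin(tree: Chronogram, bin_edges: tuple[float, float],
                    definition: str = "branches") -> int:
    """Number of lineages available in an age bin.

    ``definition="branches"`` (default): branches whose age interval
    intersects the open bin interior — the lineages alive at some point in
    the bin.  ``definition="nodes"``: branching events (internal nodes)
    whose age lies in [lo, hi).
    """
    lo, hi = float(bin_edges[0]), float(bin_edges[1])
    if definition == "branches":
        n = 0
        for c in range(tree.n_nodes):
            par = tree.parent[c]
            if par < 0:
                continue
            if tree.age[c] < hi and tree.age[par] > lo:
                n += 1
        return n
    if definition == "nodes":
        ages = tree.age[tree.n_tips:]
        return int(np.sum((ages >= lo) & (ages < hi)))
    raise ValueError(f"unknown denominator definition {definition!r}")


@dataclass
class BinnedShiftRates:
    """Relative range-shift rates per time bin per direction.

    ``rates`` has shape (n_maps, n_directions, n_bins); bins with zero
    denominator hold NaN (missing, not zero).  ``meta`` records the
    denominator definition and the actual width of the oldest bin.
    """

    bin_edges: np.ndarray
    directions: list
    direction_labels: list[str]
    counts: np.ndarray            # (n_maps, n_dir, n_bins)
    denominators: np.ndarray      # (n_bins,)
    rates: np.ndarray             # (n_maps, n_dir, n_bins), NaN if denom 0
    mean: np.ndarray              # (n_dir, n_bins)
    lo95: np.ndarray
    hi95: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for di, lab in enumerate(self.direction_labels):
            for b in range(len(self.bin_edges) - 1):
                rows.append((self.bin_edges[b], self.bin_edges[b + 1], lab,
                             self.mean[di, b], self.lo95[di, b],
                             self.hi95[di, b], self.denominators[b]))
        return pd.DataFrame(rows, columns=["bin_start", "bin_end",
                                           "direction", "mean", "lo95",
                                           "hi95", "denominator"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _default_directions(state_names: list) -> tuple[list, list[str]]:
    k = len(state_names)
    dirs, labels = [], []
    for i in range(k):
        for j in range(k):
            if i != j:
                dirs.append((i, j))
                labels.append(f"{state_names[i]}->{state_names[j]}")
    for i in range(k):
        dirs.append(("any", i))
        labels.append(f"immigration:{state_names[i]}")
        dirs.append((i, "any"))
        labels.append(f"emigration:{state_names[i]}")
    return dirs, labels


def relative_shift_rates(tree: Chronogram, tip_states: pd.Series,
                         q: np.ndarray, root_prior="stationary",
                         n_maps: int = 100, bin_width: float = 5.0,
                         seed: int = 0, denominator: str = "branches",
                         directions=None, state_names: list | None = None) \
        -> BinnedShiftRates:
    """Relative transition rates through time with empirical 95% bands.

    Draws ``n_maps`` stochastic histories, counts transitions per
    direction per age bin (bins of ``bin_width`` Myr anchored at the
    present), divides by the per-bin lineage-availability denominator, and
    summarizes across replicates by the mean and the empirical 2.5–97.5
    percentile band.
    """
    if n_maps < 2:
        raise ValueError("n_maps must be >= 2")
    mapper = _Mapper(tree, tip_states, q, root_prior, state_names)
    names = mapper.state_names
    if directions is None:
        dirs, labels = _default_directions(names)
    else:
        dirs = list(directions)
        labels = [d if isinstance(d, str) else f"{d[0]}->{d[1]}"
                  for d in dirs]
    bins = make_bins(tree.root_age, bin_width)
    nb = len(bins) - 1
    denom = np.array([lineages_in_bin(tree, (bins[b], bins[b + 1]),
                                      denominator) for b in range(nb)],
                     float)
    counts = np.zeros((n_maps, len(dirs), nb))
    for m in range(n_maps):
        hist = mapper.sample(seed=seed + m)
        for di, d in enumerate(dirs):
            counts[m, di] = count_transitions(hist, bins, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / denom[None, None, :]
    rates[:, :, denom == 0] = np.nan
    mean = rates.mean(axis=0)
    lo = np.percentile(rates, 2.5, axis=0)
    hi = np.percentile(rates, 97.5, axis=0)
    meta = {"denominator": denominator, "bin_width": bin_width,
            "n_maps": n_maps, "seed": seed,
            "oldest_bin_actual_width":
                float(tree.root_age - bins[-2]) if nb else 0.0,
            "root_prior": str(root_prior)}
    return BinnedShiftRates(bins, dirs, labels, counts, denom, rates,
                            mean, lo, hi, meta)
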