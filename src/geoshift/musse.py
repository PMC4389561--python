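"""Multi-state speciation/extinction (MuSSE) likelihood, fitting, per-clade
rate normalization and cross-region comparison.

The model: a lineage in state ``i`` speciates at rate ``lambda_i``, goes
extinct at rate ``mu_i`` and moves to state ``j`` at rate ``q_ij``; an
extant species in state ``i`` is sampled (appears in the tree) with
probability ``rho_i``.  The likelihood integrates the standard D/E
ordinary differential equations along every branch (tip conditions
``D_i = rho_i [state == i]``, ``E_i = 1 - rho_i``), multiplies sister
D vectors by ``lambda_i`` at each node, and combines states at the root
according to the chosen root mode (FitzJohn likelihood weighting by
default).

Cross-region comparison follows the mean-rate design: per clade, each
region's rate is divided by the clade's across-region sum ("normalized"
rates), then regions are compared with one-way ANOVA over clades and
Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from ._sse import musse_loglik_core
from .simulate import stationary_distribution
from .trees import Chronogram

__all__ = [
    "MusseParams", "MusseModel", "MusseResults", "RateComparison",
    "musse_loglik", "fit_musse", "fit_clades", "normalize_rates",
    "compare_regions",
]

FIT_BOUNDS = (1e-6, 10.0)      # /Myr box for ML search


@dataclass
class MusseParams:
    """Per-state rates of a MuSSE model.

    lam/mu: speciation and extinction rates (/lineage/Myr); q: k×k
    transition rate matrix; rho: per-state sampling fractions in (0, 1].
    """

    lam: np.ndarray
    mu: np.ndarray
    q: np.ndarray
    rho: np.ndarray | None = None

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, float))
        k = self.lam.shape[0]
        self.mu = np.broadcast_to(np.asarray(self.mu, float), (k,)).copy()
        q = np.asarray(self.q, float)
        if q.ndim == 0:
            q = np.full((k, k), float(q))
        if q.shape != (k, k):
            raise ValueError(f"q must be {k}x{k}")
        np.fill_diagonal(q, 0.0)
        if np.any(q < 0):
            raise ValueError("off-diagonal q must be >= 0")
        np.fill_diagonal(q, -q.sum(axis=1))
        self.q = q
        if self.rho is None:
            self.rho = np.ones(k)
        else:
            self.rho = np.broadcast_to(np.asarray(self.rho, float),
                                       (k,)).copy()
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValueError("rates must be >= 0")
        if np.any(self.rho <= 0) or np.any(self.rho > 1):
            raise ValueError("rho must be in (0, 1]")

    @property
    def k(self) -> int:
        return self.lam.shape[0]


class MusseModel:
    """State-dependent diversification model on a dated binary tree.

    Parameters
    ----------
    tree
        Ultrametric, strictly bifurcating :class:`Chronogram`.
    tip_states
        One state per tip (labels or integers).
    rho
        Per-state sampling fractions in (0, 1]; default complete sampling.
    root_mode
        ``"fitzjohn"`` (default: weight root states by their conditional
        likelihoods), ``"equilibrium"`` (stationary distribution of q),
        ``"uniform"``, or an explicit vector.
    condition_on_survival
        Divide by the probability that both root lineages leave sampled
        descendants.  Off by default; always recorded in the summary.
    """

    def __init__(self, tree: Chronogram, tip_states: pd.Series,
                 rho=None, root_mode="fitzjohn",
                 condition_on_survival: bool = False,
                 state_names: list | None = None):
        tree.assert_ultrametric()
        if not tree.is_binary:
            raise ValueError("MuSSE requires a strictly bifurcating tree")
        self.tree = tree
        ts = pd.Series(tip_states).reindex(tree.tip_labels)
        if ts.isna().any():
            raise ValueError("every tip needs a state")
        if state_names is None:
            state_names = sorted(ts.unique(), key=str)
        self.state_names = list(state_names)
        lookup = {s: i for i, s in enumerate(self.state_names)}
        try:
            self.state_idx = np.array([lookup[s] for s in ts],
                                      dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"unknown tip state {e.args[0]!r}") from None
        self.k = len(self.state_names)
        self.tip_states = ts
        self.rho = (np.ones(self.k) if rho is None
                    else np.broadcast_to(np.asarray(rho, float),
                                         (self.k,)).copy())
        observed = np.unique(self.state_idx)
        if np.any(self.rho[observed] <= 0):
            raise ValueError("rho must be > 0 for every observed state")
        if np.any(self.rho > 1) or np.any(self.rho <= 0):
            raise ValueError("rho must be in (0, 1]")
        self.root_mode = root_mode
        self.condition_on_survival = bool(condition_on_survival)
        self._post, self._left, self._right = tree.binary_arrays()
        self._tipstate = np.full(tree.n_nodes, -1, dtype=np.int64)
        self._tipstate[: tree.n_tips] = self.state_idx

    # -- likelihood ----------------------------------------------------
    def loglike(self, params: MusseParams) -> float:
        if params.k != self.k:
            raise ValueError(f"params have k={params.k}, model has "
                             f"k={self.k}")
        rho = params.rho if params.rho is not None else self.rho
        use_fj = self.root_mode == "fitzjohn"
        if use_fj:
            w = np.zeros(self.k)
        elif self.root_mode == "equilibrium":
            w = stationary_distribution(params.q)
        elif self.root_mode == "uniform":
            w = np.full(self.k, 1.0 / self.k)
        else:
            w = np.asarray(self.root_mode, float)
        ll, status = musse_loglik_core(
            self._post, self._left, self._right, self.tree.blen,
            self._tipstate, params.lam, params.mu, params.q, rho,
            use_fj, w, self.condition_on_survival)
        if status != 0:
            raise FloatingPointError(
                f"ODE integration failed on branch above node {status - 1}")
        return float(ll)

    # -- fitting -------------------------------------------------------
    def _pack(self, constraints: dict) -> tuple[list, list]:
        """Free-parameter layout given equality constraints.

        constraints: {"lambda": "free"|"equal", "mu": ..., "q":
        "free"|"sym"|"equal"}.
        """
        c = {"lambda": "free", "mu": "free", "q": "sym"}
        c.update(constraints or {})
        layout = []
        k = self.k
        for name in ("lambda", "mu"):
            layout.append((name, 1 if c[name] == "equal" else k))
        if c["q"] == "equal":
            nq = 1
        elif c["q"] == "sym":
            nq = k * (k - 1) // 2
        elif c["q"] == "free":
            nq = k * (k - 1)
        else:
            raise ValueError(f"unknown q constraint {c['q']!r}")
        layout.append(("q", nq))
        return layout, [c["lambda"], c["mu"], c["q"]]

    def _unpack(self, x: np.ndarray, layout, modes) -> MusseParams:
        k = self.k
        pos = 0
        vals = {}
        for name, n in layout:
            vals[name] = x[pos:pos + n]
            pos += n
        lam = np.full(k, vals["lambda"][0]) if len(vals["lambda"]) == 1 \
            else vals["lambda"]
        mu = np.full(k, vals["mu"][0]) if len(vals["mu"]) == 1 \
            else vals["mu"]
        qv = vals["q"]
        q = np.zeros((k, k))
        if modes[2] == "equal":
            q[:] = qv[0]
        elif modes[2] == "sym":
            it = iter(qv)
            for i in range(k):
                for j in range(i + 1, k):
                    q[i, j] = q[j, i] = next(it)
        else:
            it = iter(qv)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        q[i, j] = next(it)
        return MusseParams(lam=lam.copy(), mu=mu.copy(), q=q, rho=self.rho)

    def _starts(self, n_extra: int, seed: int) -> list[np.ndarray]:
        """Deterministic multi-starts seeded from birth-death moment
        estimates (net rate ~ ln(n/2) / root age)."""
        n = self.tree.n_tips
        t = max(self.tree.root_age, 1e-6)
        r = max(np.log(max(n, 3) / 2.0) / t, 1e-4)
        changes = max(1, int(np.sum(self.state_idx[:-1]
                                    != self.state_idx[1:])))
        q0 = changes / max(self.tree.total_length, 1e-9)
        base = [
            (r, r * 0.1, q0),
            (2.0 * r, r, q0 * 2.0),
            (0.5 * r, r * 0.05, q0 * 0.5),
        ]
        rng = np.random.default_rng(seed)
        for _ in range(n_extra):
            f = rng.uniform(0.3, 3.0, 3)
            base.append((r * f[0], r * 0.3 * f[1], q0 * f[2]))
        return base

    def fit(self, constraints: dict | None = None, starts: int = 3,
            seed: int = 0) -> "MusseResults":
        """Bounded maximum likelihood (L-BFGS-B on log rates, bounds
        [1e-6, 10]/Myr, >=3 deterministic multi-starts)."""
        if len(np.unique(self.state_idx)) < 2:
            c = constraints or {}
            collapsed = (c.get("lambda") == "equal"
                         and c.get("mu") == "equal")
            if not collapsed and self.k > 1:
                raise ValueError("all tips in one state; constrain rates "
                                 "equal or use a single-state model")
        layout, modes = self._pack(constraints)
        nf = sum(n for _, n in layout)
        lo, hi = np.log(FIT_BOUNDS[0]), np.log(FIT_BOUNDS[1])

        def nll(x):
            try:
                ll = self.loglike(self._unpack(np.exp(x), layout, modes))
            except FloatingPointError:
                return 1e10
            return -ll if np.isfinite(ll) else 1e10

        trace = []
        best = None
        for lam0, mu0, q0 in self._starts(max(0, starts - 3), seed):
            x0 = np.concatenate([
                np.full(layout[0][1], np.log(np.clip(lam0, *FIT_BOUNDS))),
                np.full(layout[1][1], np.log(np.clip(mu0, *FIT_BOUNDS))),
                np.full(layout[2][1], np.log(np.clip(q0, *FIT_BOUNDS))),
            ])
            res = scipy.optimize.minimize(nll, x0, method="L-BFGS-B",
                                          bounds=[(lo, hi)] * nf)
            trace.append({"x0": x0.tolist(), "llf": -float(res.fun),
                          "converged": bool(res.success),
                          "nfev": int(res.nfev)})
            if best is None or -res.fun > best[0]:
                best = (-float(res.fun), res)
        if best is None or not np.isfinite(best[0]):
            raise RuntimeError(f"no start converged; trace: {trace}")
        llf, res = best
        params = self._unpack(np.exp(res.x), layout, modes)
        return MusseResults(self, params, llf, bool(res.success), trace,
                            constraints=modes)


class MusseResults:
    """ML estimates of MuSSE rates with diagnostics."""

    def __init__(self, model: MusseModel, params: MusseParams, llf: float,
                 converged: bool, trace: list, constraints=None):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.converged = converged
        self.trace = trace
        self.constraints = constraints

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": self.model.state_names,
            "lambda": self.params.lam,
            "mu": self.params.mu,
            "rho": self.params.rho,
            "n_tips": [int(np.sum(self.model.state_idx == i))
                       for i in range(self.model.k)],
        })

    def summary(self) -> str:
        lines = [
            "MuSSE state-dependent diversification fit",
            "=" * 50,
            f"tips:                  {self.model.tree.n_tips}",
            f"states:                {self.model.state_names}",
            f"root mode:             {self.model.root_mode}",
            f"conditioned on surv.:  {self.model.condition_on_survival}",
            f"constraints (lam/mu/q): {self.constraints}",
            f"log-likelihood:        {self.llf:.6f}",
            f"converged:             {self.converged}",
            self.rates_frame().round(6).to_string(index=False),
            "transition rates q (/Myr):",
            pd.DataFrame(self.params.q, index=self.model.state_names,
                         columns=self.model.state_names
                         ).round(6).to_string(),
        ]
        return "\n".join(lines)


def musse_loglik(tree: Chronogram, tip_states: pd.Series,
                 params: MusseParams, root_mode="fitzjohn",
                 condition_on_survival: bool = False,
                 state_names: list | None = None) -> float:
    """MuSSE log-likelihood at fixed parameters (module-level wrapper)."""
    if state_names is None and params.k is not None:
        uniq = sorted(pd.Series(tip_states).unique(), key=str)
        if len(uniq) < params.k and all(isinstance(s, (int, np.integer))
                                        for s in uniq):
            state_names = list(range(params.k))
    model = MusseModel(tree, tip_states, rho=params.rho,
                       root_mode=root_mode,
                       condition_on_survival=condition_on_survival,
                       state_names=state_names)
    return model.loglike(params)


def fit_musse(tree: Chronogram, tip_states: pd.Series, rho=None,
              constraints: dict | None = None, seed: int = 0,
              root_mode="fitzjohn", condition_on_survival: bool = False,
              state_names: list | None = None, starts: int = 3) \
        -> MusseResults:
    """Convenience wrapper: build a :class:`MusseModel` and fit it."""
    import warnings
    if tree.n_tips < 20:
        warnings.warn(f"only {tree.n_tips} tips; MuSSE estimates will be "
                      "very noisy", stacklevel=2)
    model = MusseModel(tree, tip_states, rho=rho, root_mode=root_mode,
                       condition_on_survival=condition_on_survival,
                       state_names=state_names)
    return model.fit(constraints=constraints, starts=starts, seed=seed)


# ----------------------------------------------------------------------
# per-clade fits, normalization and comparison
# ----------------------------------------------------------------------
def fit_clades(tree: Chronogram, tip_states: pd.Series,
               clades: pd.Series, rho: dict | None = None,
               constraints: dict | None = None, min_tips: int = 20,
               seed: int = 0, state_names: list | None = None) \
        -> pd.DataFrame:
    """Fit MuSSE independently on each named clade's crown subtree.

    ``clades`` maps tip label -> clade name; ``rho`` optionally maps clade
    name -> per-state sampling fractions.  Clades with fewer than
    ``min_tips`` tips or fewer than 2 observed states are skipped (listed
    in the result with ``fitted=False``).  Returns a long-format table of
    per-clade per-state rate estimates.
    """
    if state_names is None:
        state_names = sorted(pd.Series(tip_states).unique(), key=str)
    rows = []
    for clade in sorted(pd.Series(clades).unique(), key=str):
        labels = [t for t in tree.tip_labels
                  if clades.get(t, None) == clade]
        reason = None
        if len(labels) < max(min_tips, 2):
            reason = f"only {len(labels)} tips"
        else:
            sub = tree.prune_to(labels)
            st = pd.Series(tip_states).loc[sub.tip_labels]
            if st.nunique() < 2:
                reason = "single observed state"
        if reason is not None:
            rows.append({"clade": clade, "state": None, "lambda": np.nan,
                         "mu": np.nan, "n_tips": len(labels),
                         "fitted": False, "note": reason})
            continue
        r = rho.get(clade) if rho else None
        res = fit_musse(sub, st, rho=r, constraints=constraints, seed=seed,
                        state_names=state_names)
        for i, sname in enumerate(res.model.state_names):
            rows.append({"clade": clade, "state": sname,
                         "lambda": res.params.lam[i],
                         "mu": res.params.mu[i],
                         "n_tips": int(np.sum(res.model.state_idx == i)),
                         "fitted": True, "note": "",
                         "llf": res.llf, "converged": res.converged})
    return pd.DataFrame(rows)


def normalize_rates(table: pd.DataFrame,
                    rate_cols: tuple[str, ...] = ("lambda", "mu")) \
        -> pd.DataFrame:
    """Normalize each clade's rates across regions to sum to 1.

    For every clade and rate type, each region's rate is divided by the
    clade's sum over regions.  Clades whose rates sum to 0 (or that were
    not fitted) are flagged ``excluded`` and dropped from comparisons.
    """
    if "fitted" in table.columns:
        df = table[table["fitted"].astype(bool)].copy()
    else:
        df = table.copy()
    if (df[list(rate_cols)] < 0).any().any():
        raise ValueError("rates must be >= 0")
    df["excluded"] = False
    for col in rate_cols:
        sums = df.groupby("clade")[col].transform("sum")
        zero = sums <= 0
        df.loc[zero, "excluded"] = True
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"{col}_norm"] = np.where(zero, np.nan, df[col] / sums)
    return df


@dataclass
class RateComparison:
    """One-way ANOVA + Tukey HSD of normalized rates across regions."""

    anova: pd.DataFrame                 # rate_type, F, p, n_clades
    tukey: pd.DataFrame                 # rate_type, region pair, p_adj
    means: pd.DataFrame                 # rate_type x region, mean values
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        import json
        s = json.dumps({
            "anova": self.anova.to_dict(orient="records"),
            "tukey": self.tukey.to_dict(orient="records"),
            "means": self.means.to_dict(orient="records"),
            "meta": self.meta}, indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compare_regions(normalized: pd.DataFrame,
                    rate_cols: tuple[str, ...] = ("lambda", "mu"),
                    region_col: str = "state") -> RateComparison:
    """Compare normalized rates across regions, clades as observations.

    One-way ANOVA per rate type followed by Tukey's honest significant
    difference test on the same normalized values; means are the point
    summaries.  Requires >=2 regions and >=2 clades per region.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if "excluded" in normalized.columns:
        df = normalized[~normalized["excluded"].astype(bool)].copy()
    else:
        df = normalized.copy()
    regions = sorted(df[region_col].dropna().unique(), key=str)
    if len(regions) < 2:
        raise ValueError("need >=2 regions to compare")
    anova_rows, tukey_rows, mean_rows = [], [], []
    for col in rate_cols:
        ncol = f"{col}_norm" if f"{col}_norm" in df.columns else col
        groups = []
        for r in regions:
            vals = df.loc[df[region_col] == r, ncol].dropna().to_numpy()
            if len(vals) < 2:
                raise ValueError(f"fewer than 2 clades for region {r!r}")
            groups.append(vals)
        f_stat, p = scipy.stats.f_oneway(*groups)
        anova_rows.append({"rate": col, "F": float(f_stat),
                           "p": float(p),
                           "n_per_region": [len(g) for g in groups]})
        import itertools

        vals = df[ncol].dropna()
        sub = df.loc[vals.index]
        thsd = pairwise_tukeyhsd(sub[ncol].to_numpy(),
                                 sub[region_col].astype(str).to_numpy())
        pairs = list(itertools.combinations(thsd.groupsunique, 2))
        for (g1, g2), md, p_adj, rej in zip(pairs, thsd.meandiffs,
                                            thsd.pvalues, thsd.reject):
            tukey_rows.append({"rate": col, "group1": str(g1),
                               "group2": str(g2),
                               "meandiff": float(md),
                               "p_adj": float(p_adj),
                               "reject": bool(rej)})
        for r, g in zip(regions, groups):
            mean_rows.append({"rate": col, "region": r,
                              "mean": float(np.mean(g)), "n": len(g)})
    meta = {"significance_bands": [0.05, 0.001],
            "values": "normalized (per-clade share of across-region sum)"}
    return RateComparison(pd.DataFrame(anova_rows),
                          pd.DataFrame(tukey_rows),
                          pd.DataFrame(mean_rows), meta)
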