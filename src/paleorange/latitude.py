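"""Latitudinal evolution under Brownian motion with a time-variable trend.

The latitude of a lineage evolves as Brownian motion with rate
``sigma2`` plus a piecewise-constant directional drift: time is divided
into bins and bin ``k`` contributes drift ``mu_k`` (degrees/Myr), so a
branch increment is Normal(sum_k mu_k * t_k, sigma2 * t) where ``t_k``
is the branch time spent in bin k. Tip data are extant mean latitudes
and fossil paleolatitudes; internal-node latitudes are latent variables
sampled by MCMC together with ``sigma2`` and the ``mu_k`` (node-state
augmentation). Traits are rescaled (divided) by a constant, 10 by
default, to help mixing; reported quantities are mapped back to
degrees. From the posterior samples the latitudinal span of the clade
through time is reconstructed by interpolating lineage paths on a time
grid.

Exact likelihood and prior choices of the originally published
implementation of this method are not fully specified in print; the
parameterization here (priors below) is a documented, testable
realization of the same model family.

Priors (on the rescaled scale): sigma2 ~ half-Cauchy(1); mu_k ~
Normal(0, 10^2); root state ~ Normal(0, 50^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trees import DatedTree

__all__ = [
    "TrendModel",
    "LatitudeTrendModel",
    "LatitudeTrendResults",
    "bm_trend_log_posterior",
    "run_latitude_mcmc",
    "span_through_time",
]

_MIN_BRANCH = 1e-8  # Myr; variance floor for zero-length (sampled-ancestor) edges

DEFAULT_BIN_BOUNDS = (358.9, 201.3, 66.0, 23.0, 0.0)


@dataclass
class TrendModel:
    """Parameters and latent states of the directional BM model.

    All values are on the rescaled scale (degrees / ``rescale``).
    ``bin_bounds`` are bin edges in Ma, oldest first, ending at 0;
    ``mu`` has one drift per bin (rescaled degrees per Myr).
    """

    sigma2: float
    bin_bounds: np.ndarray
    mu: np.ndarray
    node_states: np.ndarray | None = None
    rescale: float = 10.0

    def __post_init__(self):
        self.bin_bounds = np.asarray(self.bin_bounds, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if np.any(np.diff(self.bin_bounds) >= 0) or self.bin_bounds[-1] != 0:
            raise ValueError("bin_bounds must strictly decrease and end at 0 Ma")
        if len(self.mu) != len(self.bin_bounds) - 1:
            raise ValueError("need one mu per bin")

    @property
    def n_bins(self) -> int:
        return len(self.mu)


def _tree_arrays(tree: DatedTree, bin_bounds: np.ndarray):
    """Per-node parent index, branch length, and per-bin exposure matrix."""
    n = len(tree.nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    ages = np.array([nd.age for nd in tree.nodes])
    nb = len(bin_bounds) - 1
    expo = np.zeros((n, nb))
    for nd in tree.nodes:
        if nd.parent is None:
            continue
        parent[nd.index] = nd.parent.index
        blen[nd.index] = nd.branch_length
        for k in range(nb):
            older, younger = bin_bounds[k], bin_bounds[k + 1]
            expo[nd.index, k] = max(
                0.0, min(nd.parent.age, older) - max(nd.age, younger)
            )
    return parent, blen, ages, expo


def _log_prior(sigma2: float, mu: np.ndarray, root_state: float) -> float:
    lp = np.log(2.0 / np.pi) - np.log1p(sigma2 * sigma2)  # half-Cauchy(1)
    lp += -0.5 * np.sum(mu * mu) / 100.0 - len(mu) * np.log(10.0)
    lp += -0.5 * root_state * root_state / 2500.0 - np.log(50.0)
    return float(lp)


def bm_trend_log_posterior(tree: DatedTree, data: Mapping[str, float],
                           model: TrendModel) -> float:
    """Log posterior density at fixed node states.

    ``model.node_states`` holds rescaled latitudes for every node (tree
    node index order); tip entries must match ``data`` after rescaling.
    """
    if model.node_states is None:
        raise ValueError("model.node_states must be set")
    x = np.asarray(model.node_states, dtype=float)
    parent, blen, _ages, expo = _tree_arrays(tree, model.bin_bounds)
    has_parent = parent >= 0
    if np.any(blen[has_parent] < 0):
        raise ValueError("non-positive branch length")
    t = np.maximum(blen[has_parent], _MIN_BRANCH)
    drift = expo[has_parent] @ model.mu
    inc = x[has_parent] - x[parent[has_parent]]
    var = model.sigma2 * t
    ll = float(np.sum(-0.5 * np.log(2 * np.pi * var) - 0.5 * (inc - drift) ** 2 / var))
    root_idx = int(np.where(~has_parent)[0][0])
    return ll + _log_prior(model.sigma2, model.mu, x[root_idx])


class LatitudeTrendModel:
    """Directional-BM latitude model over a posterior sample of trees.

    Parameters
    ----------
    trees : DatedTree or sequence of DatedTree
        Dated tree(s); tips without latitude data are pruned.
    data : mapping label -> latitude (degrees)
        Extant mean latitudes and fossil paleolatitudes.
    bin_bounds : sequence of Ma, oldest first, ending at 0
        Trend bins (default: the four geological time slices).
    rescale : float
        Traits are divided by this before analysis (default 10).
    """

    def __init__(self, trees, data: Mapping[str, float],
                 bin_bounds: Sequence[float] = DEFAULT_BIN_BOUNDS,
                 rescale: float = 10.0):
        if isinstance(trees, DatedTree):
            trees = [trees]
        if not trees:
            raise ValueError("need at least one tree")
        self.data = dict(data)
        self.rescale = float(rescale)
        self.trees: list[DatedTree] = []
        for tr in trees:
            drop = {t.label for t in tr.tip_nodes if t.label not in self.data}
            self.trees.append(tr.prune_tips(drop) if drop else tr)
        root_age = max(tr.root_age for tr in self.trees)
        bb = [b for b in bin_bounds if b < root_age]
        self.bin_bounds = np.array([root_age] + bb, dtype=float)
        if self.bin_bounds[-1] != 0:
            self.bin_bounds = np.append(self.bin_bounds, 0.0)
        self.n_bins = len(self.bin_bounds) - 1
        self._cache = [_tree_arrays(tr, self.bin_bounds) for tr in self.trees]
        # A fossil tip attached by a zero-length branch (sampled ancestor)
        # pins its parent's latent state to the observed value; the
        # zero-length edge itself carries no density.
        self._pinned: list[dict[int, float]] = []
        self._edge_ok: list[np.ndarray] = []
        self._free_internal: list[np.ndarray] = []
        for ti, tr in enumerate(self.trees):
            parent, blen, _ages, _expo = self._cache[ti]
            pinned: dict[int, float] = {}
            edge_ok = parent >= 0
            for nd in tr.tip_nodes:
                if nd.parent is not None and nd.branch_length < 1e-9:
                    pinned[nd.parent.index] = self.data[nd.label] / self.rescale
                    edge_ok = edge_ok.copy()
                    edge_ok[nd.index] = False
            self._pinned.append(pinned)
            self._edge_ok.append(edge_ok)
            self._free_internal.append(np.array(
                [nd.index for nd in tr.internal_nodes if nd.index not in pinned],
                dtype=int))

    def _init_states(self, ti: int) -> np.ndarray:
        """Initial latent states: tips at data, internals at the mean of
        descendant tip values (postorder average)."""
        tree = self.trees[ti]
        x = np.zeros(len(tree.nodes))
        for nd in tree.postorder():
            if nd.is_tip:
                x[nd.index] = self.data[nd.label] / self.rescale
            else:
                x[nd.index] = np.mean([x[c.index] for c in nd.children])
        for idx, val in self._pinned[ti].items():
            x[idx] = val
        return x

    def _edge_loglik(self, ti: int, x, sigma2, mu) -> float:
        parent, blen, _ages, expo = self._cache[ti]
        hp = self._edge_ok[ti]
        t = np.maximum(blen[hp], _MIN_BRANCH)
        drift = expo[hp] @ mu
        inc = x[hp] - x[parent[hp]]
        var = sigma2 * t
        return float(np.sum(-0.5 * np.log(2 * np.pi * var)
                            - 0.5 * (inc - drift) ** 2 / var))

    def _local_loglik(self, ti: int, x, sigma2, mu, node: int) -> float:
        """Edge terms involving one node (its branch and its children's)."""
        parent, blen, _ages, expo = self._cache[ti]
        edge_ok = self._edge_ok[ti]
        total = 0.0
        idxs = [node] + [c.index for c in self.trees[ti].nodes[node].children]
        for i in idxs:
            p = parent[i]
            if p < 0 or not edge_ok[i]:
                continue
            t = max(blen[i], _MIN_BRANCH)
            drift = expo[i] @ mu
            inc = x[i] - x[p]
            total += -0.5 * np.log(2 * np.pi * sigma2 * t) \
                - 0.5 * (inc - drift) ** 2 / (sigma2 * t)
        return total

    def fit_mcmc(self, n_generations: int = 100_000, seed: int = 0,
                 burnin_frac: float = 0.1, thin: int = 100,
                 chunk: int = 1000, tune: bool = True
                 ) -> "LatitudeTrendResults":
        """Metropolis–Hastings sampling of sigma2, mu_k and node states.

        One generation is one elementary update (a parameter or one
        node). The tree index is resampled every ``chunk`` generations;
        latent states are re-initialized when the tree changes while
        parameters carry over. Proposal widths are auto-tuned during
        burn-in only.
        """
        rng = np.random.default_rng(seed)
        sigma2 = 1.0
        mu = np.zeros(self.n_bins)
        ti = int(rng.integers(len(self.trees)))
        x = self._init_states(ti)
        tree = self.trees[ti]
        internal = self._free_internal[ti]
        ll = self._edge_loglik(ti, x, sigma2, mu)
        widths = {"sigma2": 0.5, "mu": 0.05, "node": 1.0}
        burnin = int(burnin_frac * n_generations)
        samples = []
        acc = {"sigma2": [0, 0], "mu": [0, 0], "node": [0, 0]}
        window = {k: [0, 0] for k in acc}
        root_idx = tree.root.index

        def full_posterior(ll_val, s2, mu_v, xv):
            return ll_val + _log_prior(s2, mu_v, xv[root_idx])

        for g in range(n_generations):
            if g > 0 and g % chunk == 0 and len(self.trees) > 1:
                ti = int(rng.integers(len(self.trees)))
                tree = self.trees[ti]
                internal = self._free_internal[ti]
                root_idx = tree.root.index
                x = self._init_states(ti)
                ll = self._edge_loglik(ti, x, sigma2, mu)
            u = rng.random()
            if u < 0.05 or len(internal) == 0:  # sigma2, multiplicative
                prop = sigma2 * np.exp(widths["sigma2"] * rng.normal())
                ll_new = self._edge_loglik(ti, x, prop, mu)
                # Jacobian of the multiplicative proposal: log(prop/sigma2)
                lr = (full_posterior(ll_new, prop, mu, x)
                      - full_posterior(ll, sigma2, mu, x)
                      + np.log(prop / sigma2))
                acc["sigma2"][1] += 1
                window["sigma2"][1] += 1
                if np.log(rng.random()) < lr:
                    sigma2, ll = prop, ll_new
                    acc["sigma2"][0] += 1
                    window["sigma2"][0] += 1
            elif u < 0.30:  # one mu_k, additive
                k = int(rng.integers(self.n_bins))
                mu_new = mu.copy()
                mu_new[k] += widths["mu"] * rng.normal()
                ll_new = self._edge_loglik(ti, x, sigma2, mu_new)
                lr = (full_posterior(ll_new, sigma2, mu_new, x)
                      - full_posterior(ll, sigma2, mu, x))
                acc["mu"][1] += 1
                window["mu"][1] += 1
                if np.log(rng.random()) < lr:
                    mu, ll = mu_new, ll_new
                    acc["mu"][0] += 1
                    window["mu"][0] += 1
            else:  # one free internal node, sliding window
                i = int(internal[rng.integers(len(internal))])
                old = x[i]
                local_old = self._local_loglik(ti, x, sigma2, mu, i)
                prior_old = _log_prior(sigma2, mu, x[root_idx])
                x[i] = old + widths["node"] * (rng.random() - 0.5) * 2
                local_new = self._local_loglik(ti, x, sigma2, mu, i)
                prior_new = _log_prior(sigma2, mu, x[root_idx])
                lr = (local_new - local_old) + (prior_new - prior_old)
                acc["node"][1] += 1
                window["node"][1] += 1
                if np.log(rng.random()) < lr:
                    ll += local_new - local_old
                    acc["node"][0] += 1
                    window["node"][0] += 1
                else:
                    x[i] = old
            if tune and g < burnin and (g + 1) % 500 == 0:
                for k, (hit, tot) in window.items():
                    if tot == 0:
                        continue
                    rate = hit / tot
                    if rate > 0.45:
                        widths[k] = min(widths[k] * 1.4, 50.0)
                    elif rate < 0.15:
                        widths[k] = max(widths[k] / 1.4, 1e-4)
                window = {k: [0, 0] for k in acc}
            if g >= burnin and (g - burnin) % thin == 0:
                samples.append({
                    "tree_index": ti,
                    "sigma2": sigma2,
                    "mu": mu.copy(),
                    "node_states": x.copy(),
                })
        rates = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in acc.items()}
        if all(v[1] and v[0] == 0 for v in acc.values()):
            import warnings
            warnings.warn("MCMC accepted no proposals; check data scaling")
        return LatitudeTrendResults(self, samples, rates, seed)


class LatitudeTrendResults:
    """Posterior samples of the directional-BM model.

    Reported summaries are on the natural (degrees) scale:
    sigma2 * rescale^2 [deg^2/Myr], mu * rescale [deg/Myr].
    """

    def __init__(self, model: LatitudeTrendModel, samples: list[dict],
                 acceptance: dict, seed: int):
        if not samples:
            raise ValueError("no posterior samples retained")
        self.model = model
        self.samples = samples
        self.acceptance = acceptance
        self.seed = seed
        c = model.rescale
        self.sigma2_samples = np.array([s["sigma2"] for s in samples]) * c * c
        self.mu_samples = np.array([s["mu"] for s in samples]) * c

    def mu_interval(self, k: int, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return tuple(np.quantile(self.mu_samples[:, k], [lo, 1 - lo]))

    def summary(self) -> str:
        lines = [
            "Directional Brownian-motion latitude reconstruction",
            "=" * 54,
            f"Trees: {len(self.model.trees)}, samples: {len(self.samples)}, "
            f"seed: {self.seed}",
            f"Acceptance: " + ", ".join(
                f"{k}={v:.2f}" for k, v in self.acceptance.items()),
            "-" * 54,
            f"sigma2 [deg^2/Myr]: mean {self.sigma2_samples.mean():.4f}, "
            f"95% CI ({np.quantile(self.sigma2_samples, 0.025):.4f}, "
            f"{np.quantile(self.sigma2_samples, 0.975):.4f})",
        ]
        bb = self.model.bin_bounds
        for k in range(self.model.n_bins):
            lo, hi = self.mu_interval(k)
            lines.append(
                f"mu[{bb[k]:.1f}-{bb[k + 1]:.1f} Ma] [deg/Myr]: "
                f"mean {self.mu_samples[:, k].mean():+.4f}, "
                f"95% CI ({lo:+.4f}, {hi:+.4f})"
            )
        return "\n".join(lines)

    def span_through_time(self, grid: Sequence[float] | None = None,
                          quantiles: tuple[float, float] | None = (0.025, 0.975)
                          ) -> pd.DataFrame:
        return span_through_time(self, grid=grid, quantiles=quantiles)


def run_latitude_mcmc(trees, data: Mapping[str, float],
                      bin_bounds: Sequence[float] = DEFAULT_BIN_BOUNDS,
                      n_generations: int = 100_000, seed: int = 0,
                      **kw) -> LatitudeTrendResults:
    """Functional wrapper: build the model and run the sampler."""
    model = LatitudeTrendModel(trees, data, bin_bounds=bin_bounds)
    return model.fit_mcmc(n_generations=n_generations, seed=seed, **kw)


def span_through_time(results: LatitudeTrendResults,
                      grid: Sequence[float] | None = None,
                      quantiles: tuple[float, float] | None = (0.025, 0.975)
                      ) -> pd.DataFrame:
    """Latitudinal span envelope on a time grid.

    For each posterior sample, lineage latitudes at each grid time are
    linear interpolations between the sampled node states bracketing
    that time on the sample's tree; the envelope pools all lineage
    values per time. ``quantiles=None`` gives the absolute min/max
    envelope; otherwise the pooled quantile envelope (default
    2.5–97.5%).
    """
    model = results.model
    root_age = max(tr.root_age for tr in model.trees)
    if grid is None:
        grid = np.linspace(root_age, 0.0, 100)
    grid = np.clip(np.asarray(grid, dtype=float), 0.0, root_age)
    c = model.rescale
    pooled: list[list[float]] = [[] for _ in grid]
    for s in results.samples:
        tree = model.trees[s["tree_index"]]
        x = s["node_states"] * c
        for gi, t in enumerate(grid):
            if t > tree.root_age:
                continue
            vals = pooled[gi]
            for nd in tree.nodes:
                if nd.parent is None:
                    if abs(nd.age - t) < 1e-9:
                        vals.append(x[nd.index])
                    continue
                if nd.age <= t <= nd.parent.age:
                    dt = nd.parent.age - nd.age
                    if dt < 1e-12:
                        vals.append(x[nd.index])
                    else:
                        f = (t - nd.age) / dt
                        vals.append(x[nd.index] * (1 - f) + x[nd.parent.index] * f)
    rows = []
    for t, vals in zip(grid, pooled):
        if not vals:
            continue
        arr = np.asarray(vals)
        if quantiles is None:
            lo, hi = arr.min(), arr.max()
        else:
            lo, hi = np.quantile(arr, quantiles)
        rows.append({"time_Ma": t, "lat_min": lo, "lat_max": hi})
    return pd.DataFrame(rows)
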