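"""Time-stratified dispersal–extinction–cladogenesis (DEC) model.

DEC treats a lineage's geographic range as a state of a continuous-time
Markov chain over sets of areas. Along branches the range evolves
anagenetically: a lineage expands into an adjacent area (dispersal, rate
``d`` per source–destination pair) or loses an occupied area
(extirpation, rate ``e`` per area); losing the last area is global
extinction, an absorbing null state. At speciation the ancestral range
is partitioned between the daughters (sympatry for single-area ranges;
subset sympatry or vicariance for widespread ones), uniformly over the
allowed scenarios. Connectivity between areas is piecewise-constant in
time (a :class:`~paleorange.geography.GeoModel`): within each time slice
only ranges that are connected under that slice's adjacency are
reachable, and dispersal is gated by adjacency.

The model is fitted by maximum likelihood with Felsenstein pruning on a
dated tree whose tips may be fossils (sampled above the present). Fossil
tips may be coded ambiguously: presence known for the observed areas,
absence elsewhere unknown, so every superset range has tip likelihood 1.

The public surface follows the statsmodels convention:
``DECModel(tree, observations, geo).fit()`` returns a
:class:`DECResults` carrying the rate estimates, their uncertainties and
the ancestral-range machinery.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
from scipy.sparse.linalg import expm_multiply

from .geography import NULL_RANGE, GeoModel, range_to_codes
from .trees import DatedTree

__all__ = [
    "DECParams",
    "TipRangeObservation",
    "DECModel",
    "DECResults",
    "AncestralRangeTable",
    "build_rate_matrix",
    "cladogenesis_distribution",
    "tip_likelihood_vector",
    "dec_log_likelihood",
    "fit_dec",
    "ancestral_ranges",
]

_DENSE_CUTOFF = 160  # state-space size below which dense expm is used
_RATE_BOUNDS = (1e-8, 10.0)  # events /lineage /Myr


@dataclass(frozen=True)
class DECParams:
    """Anagenetic rates: dispersal ``d`` (per source–destination pair per
    Myr) and extirpation ``e`` (per occupied area per Myr)."""

    d: float
    e: float

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TipRangeObservation:
    """Observed range of one tip.

    ``ambiguous=True`` means presence is asserted only for
    ``observed_areas``; absence elsewhere is unknown (fossil '?' coding),
    so any range containing the observed areas is compatible.
    """

    label: str
    observed_areas: int
    ambiguous: bool = False

    def __post_init__(self):
        if self.observed_areas == NULL_RANGE:
            raise ValueError(f"tip {self.label!r}: observed range is empty")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def build_rate_matrix(geo: GeoModel, slice_index: int, params: DECParams
                      ) -> scipy.sparse.csr_matrix:
    """Anagenetic generator over ``geo.global_state_space`` for one slice.

    Rows of ranges not allowed in the slice (and the null row) are zero;
    dispersal into area ``a`` is weighted by the number of occupied areas
    adjacent to ``a`` under the slice's adjacency; extirpations whose
    remainder range is not in the slice's allowed set are dropped.
    """
    if not 0 <= slice_index < len(geo.slices):
        raise IndexError(f"slice index {slice_index} out of bounds")
    adj = geo.slices[slice_index].adjacency
    allowed = geo.allowed_ranges_per_slice[slice_index]
    sidx = geo.state_index
    n = geo.n_states
    rows, cols, vals = [], [], []
    for mask in allowed:
        i = sidx[mask]
        occupied = [a for a in range(geo.n_areas) if mask >> a & 1]
        # dispersal: gain one adjacent area
        if len(occupied) < geo.max_range_size:
            for a in range(geo.n_areas):
                if mask >> a & 1:
                    continue
                nsources = sum(adj[b, a] for b in occupied)
                if nsources == 0:
                    continue
                target = mask | (1 << a)
                if target in allowed:
                    rows.append(i)
                    cols.append(sidx[target])
                    vals.append(params.d * nsources)
        # extirpation: lose one occupied area (null if the last)
        for a in occupied:
            target = mask & ~(1 << a)
            if target == NULL_RANGE or target in allowed:
                rows.append(i)
                cols.append(sidx.get(target, 0))
                vals.append(params.e)
    q = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    q.setdiag(-np.asarray(q.sum(axis=1)).ravel())
    return q


def cladogenesis_distribution(parent_range: int) -> list[tuple[int, int, float]]:
    """Uniform distribution over DEC cladogenetic outcomes.

    Single-area parent: identical inheritance. Widespread parent:
    subset sympatry (one daughter a single occupied area, the other the
    full range; both orders) and vicariance (disjoint split covering the
    range with at least one single-area daughter; both orders).
    """
    if parent_range == NULL_RANGE:
        raise ValueError("null parent range")
    areas = [a for a in range(parent_range.bit_length()) if parent_range >> a & 1]
    if len(areas) == 1:
        return [(parent_range, parent_range, 1.0)]
    outcomes: dict[tuple[int, int], None] = {}
    for a in areas:
        single = 1 << a
        outcomes[(single, parent_range)] = None   # subset sympatry
        outcomes[(parent_range, single)] = None
        rest = parent_range & ~single             # vicariance
        outcomes[(single, rest)] = None
        outcomes[(rest, single)] = None
    p = 1.0 / len(outcomes)
    return [(l, r, p) for l, r in outcomes]


def tip_likelihood_vector(obs: TipRangeObservation, geo: GeoModel) -> np.ndarray:
    """Tip conditional likelihood over the global state space."""
    if obs.observed_areas >> geo.n_areas:
        raise ValueError(f"tip {obs.label!r}: observed area outside the area list")
    v = np.zeros(geo.n_states)
    for i, mask in enumerate(geo.global_state_space):
        if mask == NULL_RANGE:
            continue
        if obs.ambiguous:
            v[i] = 1.0 if (mask & obs.observed_areas) == obs.observed_areas else 0.0
        else:
            v[i] = 1.0 if mask == obs.observed_areas else 0.0
    return v


def _branch_segments(geo: GeoModel, t_young: float, t_old: float
                     ) -> list[tuple[int, float]]:
    """(slice_index, duration) pieces of [t_young, t_old], youngest first."""
    if t_old <= t_young:
        return []
    cuts = [t_young]
    for sl in reversed(geo.slices):  # youngest first
        for b in (sl.younger_bound, sl.older_bound):
            if t_young < b < t_old:
                cuts.append(b)
    cuts = sorted(set(cuts)) + [t_old]
    return [
        (geo.slice_at(0.5 * (lo + hi)), hi - lo)
        for lo, hi in zip(cuts[:-1], cuts[1:])
        if hi - lo > 1e-12
    ]


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

class DECModel:
    """Maximum-likelihood DEC on a dated tree.

    Parameters
    ----------
    tree : DatedTree
        Binary dated tree; fossil tips end above the present.
    observations : mapping or sequence of TipRangeObservation
        One observation per tip label.
    geo : GeoModel
        Areas, time slices, adjacency and the range state space.
    condition_on_survival : bool
        If True, divide the likelihood by the probability that every
        sampled tip lineage avoids the null (extinct) state on this
        tree, computed by a second pruning pass with uninformative
        (all-non-null) tip vectors. Classic Lagrange/DECX leaves this
        off (the default); switch it on when tips were filtered for
        survival, otherwise the extirpation rate is biased toward zero.
    """

    def __init__(self, tree: DatedTree, observations, geo: GeoModel,
                 condition_on_survival: bool = False):
        self.tree = tree
        self.geo = geo
        self.condition_on_survival = condition_on_survival
        if not isinstance(observations, Mapping):
            observations = {o.label: o for o in observations}
        self.observations: dict[str, TipRangeObservation] = dict(observations)
        missing = [t.label for t in tree.tip_nodes if t.label not in self.observations]
        if missing:
            raise ValueError(f"tips without range observations: {missing[:5]}")
        if tree.root_age > geo.oldest_bound + 1e-9:
            raise ValueError(
                f"root age {tree.root_age:.2f} Ma exceeds the slice tiling "
                f"({geo.oldest_bound:.2f} Ma)"
            )
        self._prepare()

    # -- static structure --------------------------------------------------

    def _prepare(self) -> None:
        geo = self.geo
        n = geo.n_states
        self._slice_masks = [
            np.isin(np.arange(n), geo.allowed_state_indices(k))
            for k in range(len(geo.slices))
        ]
        # tip vectors and per-node slice masks
        self._tipvec = {}
        for t in self.tree.tip_nodes:
            v = tip_likelihood_vector(self.observations[t.label], geo)
            v *= self._slice_mask(t.age)
            if not v.any():
                raise ValueError(
                    f"tip {t.label!r}: no allowed state is compatible with its "
                    "observed range at its age"
                )
            self._tipvec[t.label] = v
        self._branch_segs = {
            node.index: _branch_segments(geo, node.age, node.parent.age)
            for node in self.tree.nodes if node.parent is not None
        }
        # cladogenesis scenario arrays per node-slice, indexed into the space
        self._clado: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        p_arr, l_arr, r_arr, w_arr = [], [], [], []
        for mask in geo.global_state_space:
            if mask == NULL_RANGE:
                continue
            for l, r, w in cladogenesis_distribution(mask):
                li = geo.state_index.get(l)
                ri = geo.state_index.get(r)
                if li is None or ri is None:
                    continue  # daughter range disconnected everywhere
                p_arr.append(geo.state_index[mask])
                l_arr.append(li)
                r_arr.append(ri)
                w_arr.append(w)
        self._scen = (
            np.array(p_arr, dtype=np.intp),
            np.array(l_arr, dtype=np.intp),
            np.array(r_arr, dtype=np.intp),
            np.array(w_arr),
        )
        # Lagrange convention: the root likelihood is the plain sum over
        # ranges allowed in the root's slice (flat unnormalized prior)
        root_slice = geo.slice_at(self.tree.root_age)
        self._root_prior = self._slice_masks[root_slice].astype(float)
        self._dense = geo.n_states <= _DENSE_CUTOFF

    def _slice_mask(self, age: float) -> np.ndarray:
        return self._slice_masks[self.geo.slice_at(age)].astype(float)

    # -- likelihood ---------------------------------------------------------

    def _generators(self, params: DECParams):
        qs = [build_rate_matrix(self.geo, k, params) for k in range(len(self.geo.slices))]
        if self._dense:
            return [q.toarray() for q in qs]
        return qs

    def _propagate_up(self, qs, v: np.ndarray, segs) -> np.ndarray:
        """Partial likelihood from the bottom to the top of a branch."""
        for k, dt in segs:
            if self._dense:
                v = scipy.linalg.expm(qs[k] * dt) @ v
            else:
                v = expm_multiply(qs[k] * dt, v)
        return v

    def _propagate_down(self, qs, v: np.ndarray, segs) -> np.ndarray:
        """Outside likelihood from the top to the bottom of a branch."""
        for k, dt in reversed(segs):
            if self._dense:
                v = scipy.linalg.expm(qs[k].T * dt) @ v
            else:
                v = expm_multiply((qs[k] * dt).T, v)
        return v

    def _combine(self, left_corner: np.ndarray, right_corner: np.ndarray) -> np.ndarray:
        p, l, r, w = self._scen
        out = np.zeros_like(left_corner)
        np.add.at(out, p, w * left_corner[l] * right_corner[r])
        return out

    def _uppass(self, params: DECParams, tipvec=None, qs=None):
        """Postorder pass.

        Returns (node partials B, corner partials S, log scaling per node,
        generators); ``B[i]`` is the conditional likelihood of the data
        below node i given its state, rescaled, ``S[i]`` the same quantity
        propagated to the parent-side end of node i's branch. ``tipvec``
        overrides the observed tip vectors (used for the survival
        denominator).
        """
        if qs is None:
            qs = self._generators(params)
        if tipvec is None:
            tipvec = self._tipvec
        nn = len(self.tree.nodes)
        B = np.zeros((nn, self.geo.n_states))
        S = np.zeros_like(B)
        logscale = np.zeros(nn)
        for node in self.tree.postorder():
            i = node.index
            if node.is_tip:
                B[i] = tipvec[node.label]
            else:
                c0, c1 = node.children
                B[i] = self._combine(S[c0.index], S[c1.index])
                B[i] *= self._slice_mask(node.age)
                logscale[i] = logscale[c0.index] + logscale[c1.index]
            m = B[i].max()
            if not np.isfinite(m) or m <= 0:
                raise ValueError(
                    f"non-finite or zero partial likelihood at node index {i} "
                    f"(label {node.label!r}, age {node.age:.3f} Ma)"
                )
            B[i] /= m
            logscale[i] += np.log(m)
            if node.parent is not None:
                S[i] = self._propagate_up(qs, B[i], self._branch_segs[i])
        return B, S, logscale, qs

    def loglike(self, params: DECParams) -> float:
        """Log-likelihood of the tip ranges under the DEC process."""
        B, _, logscale, qs = self._uppass(params)
        ridx = self.tree.root.index
        lik = float(self._root_prior @ B[ridx])
        if lik <= 0 or not np.isfinite(lik):
            raise ValueError("non-finite likelihood at the root")
        lnl = np.log(lik) + logscale[ridx]
        if self.condition_on_survival:
            lnl -= self._log_survival_prob(params, qs)
        return float(lnl)

    def _log_survival_prob(self, params: DECParams, qs) -> float:
        """Log P(every sampled tip lineage is non-null) on this tree:
        the same pruning pass with uninformative non-null tip vectors."""
        surv = {
            t.label: self._slice_mask(t.age) for t in self.tree.tip_nodes
        }
        B, _, logscale, _ = self._uppass(params, tipvec=surv, qs=qs)
        ridx = self.tree.root.index
        lik = float(self._root_prior @ B[ridx])
        return float(np.log(lik) + logscale[ridx])

    # -- fitting ------------------------------------------------------------

    def fit(self, starts: Sequence[tuple[float, float]] | None = None,
            maxiter: int = 200) -> "DECResults":
        """Maximize the likelihood over (d, e).

        Bounded quasi-Newton (L-BFGS-B) on log-transformed rates from
        multiple starting points; the best converged solution wins.
        """
        if starts is None:
            starts = [(0.01, 0.01), (0.1, 0.02), (0.001, 0.005)]
        lb, ub = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])

        def nll(x):
            try:
                return -self.loglike(DECParams(*np.exp(x)))
            except (ValueError, FloatingPointError):
                return 1e12

        attempts = []
        for d0, e0 in starts:
            res = scipy.optimize.minimize(
                nll, np.log([d0, e0]), method="L-BFGS-B",
                bounds=[(lb, ub)] * 2, options={"maxiter": maxiter},
            )
            attempts.append(res)
        finite = [r for r in attempts if np.isfinite(r.fun) and r.fun < 1e11]
        if not finite:
            raise RuntimeError(f"optimizer failed from all starts: {attempts[-1].message}")
        best = min(finite, key=lambda r: r.fun)
        params = DECParams(*np.exp(best.x))
        report = {
            "converged": bool(best.success),
            "message": str(best.message),
            "n_starts": len(starts),
            "n_starts_ok": len(finite),
            "nit": int(best.nit),
        }
        return DECResults(self, params, -float(best.fun), report)


def dec_log_likelihood(tree: DatedTree, observations, geo: GeoModel,
                       params: DECParams, **kw) -> float:
    """Functional wrapper around :meth:`DECModel.loglike`."""
    return DECModel(tree, observations, geo, **kw).loglike(params)


def fit_dec(tree: DatedTree, observations, geo: GeoModel, **kw) -> "DECResults":
    """Functional wrapper around :meth:`DECModel.fit`."""
    return DECModel(tree, observations, geo).fit(**kw)


# ---------------------------------------------------------------------------
# Results and ancestral ranges
# ---------------------------------------------------------------------------

class AncestralRangeTable:
    """Per-node ranked marginal range probabilities.

    ``ranked[i]`` lists (range bitmask, relative probability) for node
    index ``i``, best first; ``equally_likely[i]`` is the set of ranges
    whose log marginal likelihood is within 2 units of the best.
    """

    def __init__(self, tree: DatedTree, geo: GeoModel,
                 ranked: dict[int, list[tuple[int, float]]],
                 equally_likely: dict[int, set[int]]):
        self.tree = tree
        self.geo = geo
        self.ranked = ranked
        self.equally_likely = equally_likely

    def best(self, node_index: int) -> int:
        return self.ranked[node_index][0][0]

    def best_probability(self, node_index: int) -> float:
        return self.ranked[node_index][0][1]

    def probability_of(self, node_index: int, mask: int) -> float:
        for m, p in self.ranked[node_index]:
            if m == mask:
                return p
        return 0.0

    def to_frame(self, top_k: int = 3) -> pd.DataFrame:
        rows = []
        for node in self.tree.postorder():
            i = node.index
            entry = {
                "node": i,
                "label": node.label or "",
                "age_Ma": node.age,
                "is_tip": node.is_tip,
                "n_equally_likely": len(self.equally_likely[i]),
            }
            for k, (mask, p) in enumerate(self.ranked[i][:top_k], start=1):
                entry[f"range_{k}"] = range_to_codes(mask, self.geo.areas)
                entry[f"relprob_{k}"] = p
            rows.append(entry)
        return pd.DataFrame(rows)


class DECResults:
    """Fitted DEC model: rate estimates, uncertainty, diagnostics.

    Standard errors come from the observed information (numerical Hessian
    of the negative log-likelihood in log-rate space, delta method back
    to the natural scale); they are asymptotic and can be unstable when a
    rate sits on the boundary.
    """

    def __init__(self, model: DECModel, params: DECParams, llf: float,
                 report: dict):
        self.model = model
        self.params = params
        self.llf = llf
        self.report = report
        self._bse: tuple[float, float] | None = None
        self._anc: AncestralRangeTable | None = None

    @property
    def converged(self) -> bool:
        return self.report.get("converged", False)

    def bse(self) -> tuple[float, float]:
        """Approximate standard errors of (d, e)."""
        if self._bse is None:
            x0 = np.log([max(self.params.d, 1e-8), max(self.params.e, 1e-8)])
            h = 1e-4

            def f(x):
                try:
                    return -self.model.loglike(DECParams(*np.exp(x)))
                except ValueError:
                    return np.inf

            hess = np.zeros((2, 2))
            for a in range(2):
                for b in range(2):
                    xpp = x0.copy(); xpp[a] += h; xpp[b] += h
                    xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
                    xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
                    xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
                    hess[a, b] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
            try:
                cov = np.linalg.inv(hess)
                se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se_log = np.array([np.nan, np.nan])
            self._bse = (
                float(self.params.d * se_log[0]),
                float(self.params.e * se_log[1]),
            )
        return self._bse

    def ancestral_ranges(self) -> AncestralRangeTable:
        """Marginal ancestral-range probabilities at every node.

        Combines the below-node partial likelihoods from the pruning pass
        with outside likelihoods from a preorder (re-rooting) pass; per
        node the marginals are normalized to 1 and ranked, and the
        "equally likely" set collects ranges within 2 log-likelihood
        units of the best.
        """
        if self._anc is not None:
            return self._anc
        m = self.model
        B, S, logscale, qs = m._uppass(self.params)
        nn = len(m.tree.nodes)
        O = np.zeros_like(B)  # outside likelihood at node level
        ridx = m.tree.root.index
        O[ridx] = m._root_prior
        p_arr, l_arr, r_arr, w_arr = m._scen
        for node in m.tree.preorder():
            if node.is_tip:
                continue
            c0, c1 = node.children
            On = O[node.index]
            # outside at the parent-side corner of each daughter branch
            a0 = np.zeros(m.geo.n_states)
            a1 = np.zeros(m.geo.n_states)
            contrib = w_arr * On[p_arr]
            np.add.at(a0, l_arr, contrib * S[c1.index][r_arr])
            np.add.at(a1, r_arr, contrib * S[c0.index][l_arr])
            for child, a in ((c0, a0), (c1, a1)):
                v = m._propagate_down(qs, a, m._branch_segs[child.index])
                v *= m._slice_mask(child.age)
                mx = v.max()
                O[child.index] = v / mx if mx > 0 else v
        ranked: dict[int, list[tuple[int, float]]] = {}
        eq: dict[int, set[int]] = {}
        space = m.geo.global_state_space
        for node in m.tree.postorder():
            i = node.index
            marg = O[i] * B[i]
            total = marg.sum()
            if total <= 0:
                raise ValueError(f"zero marginal likelihood at node {i}")
            rel = marg / total
            order = sorted(
                (j for j in range(1, len(space)) if rel[j] > 0),
                key=lambda j: (-rel[j], space[j].bit_count(), space[j]),
            )
            ranked[i] = [(space[j], float(rel[j])) for j in order]
            if order:
                logbest = np.log(marg[order[0]])
                eq[i] = {
                    space[j] for j in order if np.log(marg[j]) >= logbest - 2.0
                }
            else:
                eq[i] = set()
        self._anc = AncestralRangeTable(m.tree, m.geo, ranked, eq)
        return self._anc

    def summary(self) -> str:
        d_se, e_se = self.bse()
        lines = [
            "Time-stratified DEC maximum-likelihood fit",
            "=" * 46,
            f"Tips: {self.model.tree.n_tips} "
            f"({len(self.model.tree.fossil_tips())} fossil), "
            f"root age {self.model.tree.root_age:.2f} Ma",
            f"Areas: {self.model.geo.n_areas}, "
            f"slices: {len(self.model.geo.slices)}, "
            f"states: {self.model.geo.n_states}",
            "-" * 46,
            f"{'param':<12}{'estimate':>12}{'std err':>12}",
            f"{'d (disp.)':<12}{self.params.d:>12.6f}{d_se:>12.6f}",
            f"{'e (extirp.)':<12}{self.params.e:>12.6f}{e_se:>12.6f}",
            "-" * 46,
            f"log-likelihood: {self.llf:.4f}",
            f"converged: {self.converged} ({self.report.get('message', '')})",
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "d": self.params.d,
            "e": self.params.e,
            "lnL": self.llf,
            "converged": self.converged,
            "report": self.report,
            "n_tips": self.model.tree.n_tips,
            "n_states": self.model.geo.n_states,
        }


def ancestral_ranges(tree: DatedTree, observations, geo: GeoModel,
                     params: DECParams) -> AncestralRangeTable:
    """Marginal ancestral ranges at fixed parameters (typically the MLE)."""
    model = DECModel(tree, observations, geo)
    res = DECResults(model, params, model.loglike(params), {"converged": True})
    return res.ancestral_ranges()
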