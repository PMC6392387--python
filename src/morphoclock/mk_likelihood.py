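"""Mk likelihood of discrete characters on a timetree.

The Mk model is a k-state continuous-time Markov chain with equal rates
between every ordered state pair and a uniform equilibrium — the
morphological analogue of Jukes–Cantor (Lewis 2001).  With a branch length
of nu expected changes per character the transition probabilities have the
closed form

    p_same(nu) = 1/k + (k-1)/k * exp(-k*nu/(k-1))
    p_diff(nu) = 1/k -   1/k   * exp(-k*nu/(k-1))

Likelihoods are computed by Felsenstein pruning, vectorised over characters
and discrete-gamma rate categories with per-node rescaling of partials, and
optionally conditioned on a character being variable among the sampled taxa
(the Mkv ascertainment-bias correction: matrices are typically scored only
for characters that vary, which inflates apparent rates if uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import special

from .morph_matrix_io import MISSING, CharacterMatrix, PartitionScheme
from .trees import TimeTree

__all__ = [
    "AscertainmentMode",
    "SiteRateModel",
    "mk_transition_matrix",
    "discrete_gamma_rates",
    "prune_character_loglik",
    "prob_variable",
    "matrix_loglik",
    "MkPartitionedLikelihood",
]

# AscertainmentMode: fixed per run
NONE = "none"
CONDITION_ON_VARIABLE = "condition_on_variable"
ASCERTAINMENT_MODES = (NONE, CONDITION_ON_VARIABLE)


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete-gamma among-character rate variation (equal-weight bins)."""

    alpha: float = 1.0
    n_categories: int = 4

    def rates(self) -> np.ndarray:
        if self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_categories)


def mk_transition_matrix(k: int, nu: float) -> np.ndarray:
    """k x k Mk transition-probability matrix at nu expected changes."""
    if k < 2:
        raise ValueError("Mk requires k >= 2 states")
    if nu < 0:
        raise ValueError("branch length nu must be >= 0")
    e = np.exp(-k * nu / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = 1.0 / k - e / k
    out = np.full((k, k), p_diff)
    np.fill_diagonal(out, p_same)
    return out


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-bin discrete-gamma category rates (Yang 1994), mean 1.

    The Gamma(alpha, alpha) distribution is cut at equal-probability
    quantiles and each category rate is the conditional mean of its bin,
    computed from the regularised incomplete gamma function.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    edges = special.gammaincinv(alpha, np.arange(1, n_categories) / n_categories) / alpha
    # P(X <= x) mass-weighted mean: E[X; X<=x] = gammainc(alpha+1, alpha*x)
    cum = special.gammainc(alpha + 1, alpha * edges)
    cum = np.concatenate(([0.0], cum, [1.0]))
    rates = np.diff(cum) * n_categories
    return rates


# ---------------------------------------------------------------------------
# pruning kernels


@njit(cache=True)
def _prune_kernel(post, ch, etab, kvec, partial, logG):  # pragma: no cover
    """Per-character log-likelihoods by postorder pruning.

    post: internal node indices (children first, root last)
    ch:   (n_internal, 2) child indices, row j for node n_tips + j
    etab: (n_nodes, G, kmax+1) precomputed exp(-k nu_b rate_g / (k-1))
    kvec: (C,) per-character state count
    partial: (n_nodes, C, kmax) workspace; tip rows hold the (constant)
        tip partials, internal rows are overwritten
    logG: (G, C) workspace for per-category log-likelihoods
    """
    n_nodes, C, kmax = partial.shape
    n_tips = (n_nodes + 1) // 2
    G = etab.shape[1]
    trans = np.empty(kmax)
    for g in range(G):
        logscale = np.zeros(C)
        for i in range(post.shape[0]):
            v = post[i]
            c0 = ch[v - n_tips, 0]
            c1 = ch[v - n_tips, 1]
            for c in range(C):
                k = kvec[c]
                # child 0
                e = etab[c0, g, k]
                pd = (1.0 - e) / k
                S = 0.0
                for j in range(k):
                    S += partial[c0, c, j]
                for j in range(k):
                    trans[j] = pd * S + e * partial[c0, c, j]
                # child 1, multiplied in
                e = etab[c1, g, k]
                pd = (1.0 - e) / k
                S = 0.0
                for j in range(k):
                    S += partial[c1, c, j]
                mx = 0.0
                for j in range(k):
                    val = trans[j] * (pd * S + e * partial[c1, c, j])
                    partial[v, c, j] = val
                    if val > mx:
                        mx = val
                if mx > 0.0 and (mx < 1e-140 or mx > 1e140):
                    for j in range(k):
                        partial[v, c, j] /= mx
                    logscale[c] += np.log(mx)
        root = n_nodes - 1
        for c in range(C):
            k = kvec[c]
            tot = 0.0
            for j in range(k):
                tot += partial[root, c, j]
            logG[g, c] = np.log(tot / k) + logscale[c]
    # average over categories in log space
    out = np.empty(C)
    for c in range(C):
        mx = logG[0, c]
        for g in range(1, G):
            if logG[g, c] > mx:
                mx = logG[g, c]
        acc = 0.0
        for g in range(G):
            acc += np.exp(logG[g, c] - mx)
        out[c] = mx + np.log(acc / G)
    return out


def _tip_partials(n_nodes: int, tip_states: np.ndarray, kvec: np.ndarray) -> np.ndarray:
    """Workspace with the constant tip rows filled in."""
    n_tips, C = tip_states.shape
    kmax = int(kvec.max(initial=2))
    partial = np.zeros((n_nodes, C, kmax))
    for t in range(n_tips):
        for c in range(C):
            s = tip_states[t, c]
            if s < 0:
                partial[t, c, : kvec[c]] = 1.0
            else:
                partial[t, c, s] = 1.0
    return partial


def _exp_table(nu: np.ndarray, site_rates: np.ndarray, kmax: int) -> np.ndarray:
    """exp(-k nu_b rate_g / (k-1)) for every node, category and k."""
    ks = np.arange(kmax + 1, dtype=np.float64)
    fac = np.zeros(kmax + 1)
    fac[2:] = ks[2:] / (ks[2:] - 1.0)
    return np.exp(-nu[:, None, None] * site_rates[None, :, None] * fac[None, None, :])


def _char_logliks(
    tree: TimeTree,
    nu: np.ndarray,
    tip_states: np.ndarray,
    kvec: np.ndarray,
    site_rates: np.ndarray,
    workspace: np.ndarray | None = None,
) -> np.ndarray:
    kvec = np.ascontiguousarray(kvec, dtype=np.int64)
    if workspace is None:
        workspace = _tip_partials(tree.n_nodes, np.asarray(tip_states, np.int16), kvec)
    kmax = workspace.shape[2]
    etab = _exp_table(np.asarray(nu, np.float64), np.asarray(site_rates, np.float64),
                      kmax)
    logG = np.empty((len(site_rates), workspace.shape[1]))
    return _prune_kernel(
        tree.postorder_internal,
        tree.children,
        etab,
        kvec,
        workspace,
        logG,
    )


# ---------------------------------------------------------------------------
# reference (single character) implementations


def prune_character_loglik(
    tree: TimeTree,
    branch_lengths: np.ndarray,
    column: np.ndarray,
    k: int,
    site_rates: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one character column by postorder pruning.

    Plain-numpy reference path; ``branch_lengths`` holds per-node
    parent-edge expected changes (rate x duration).  Missing tips carry a
    partial vector of ones; the root is averaged over the uniform
    equilibrium and, when several site-rate categories are given, over
    equal-weight categories.
    """
    column = np.asarray(column)
    if ((column >= k) & (column != MISSING)).any():
        raise ValueError(f"column contains states >= k={k}")
    rates = np.ones(1) if site_rates is None else np.asarray(site_rates, float)
    liks = np.empty(len(rates))
    for g, r in enumerate(rates):
        partial = np.zeros((tree.n_nodes, k))
        for t in range(tree.n_tips):
            if column[t] == MISSING:
                partial[t] = 1.0
            else:
                partial[t, column[t]] = 1.0
        for v in tree.postorder_internal:
            prod = np.ones(k)
            for c in tree.children_of(int(v)):
                P = mk_transition_matrix(k, branch_lengths[c] * r)
                prod *= P @ partial[c]
            partial[v] = prod
        liks[g] = partial[tree.root].sum() / k
    return float(np.log(liks.mean()))


def prob_variable(
    tree: TimeTree,
    branch_lengths: np.ndarray,
    k: int,
    site_rates: np.ndarray | None = None,
) -> float:
    """Probability that a character is variable among the sampled tips.

    1 minus the summed probabilities of the k constant patterns; this is
    the normalising constant of the variable-characters-only (Mkv)
    likelihood.  Returns 0 when all branch lengths are 0.
    """
    rates = np.ones(1) if site_rates is None else np.asarray(site_rates, float)
    p_const = 0.0
    for s in range(k):
        col = np.full(tree.n_tips, s, dtype=np.int16)
        p_const += np.exp(prune_character_loglik(tree, branch_lengths, col, k, rates))
    return max(0.0, 1.0 - p_const)


# ---------------------------------------------------------------------------
# partitioned matrix likelihood


class MkPartitionedLikelihood:
    """Fast partitioned Mk likelihood on a fixed topology.

    Characters are grouped by partition; within a partition they may have
    different state counts k.  Each partition carries its own branch-rate
    vector and gamma shape; the ascertainment mode applies per character,
    dividing by that character's probability of being variable.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        tree: TimeTree,
        scheme: PartitionScheme,
        n_categories: int = 4,
        ascertainment: str = NONE,
    ):
        if ascertainment not in ASCERTAINMENT_MODES:
            raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
        scheme.validate(matrix)
        if matrix.n_chars and matrix.declared_k.min() < 2:
            raise ValueError("characters with k < 2 must be dropped upstream")
        order = {t: i for i, t in enumerate(matrix.taxa)}
        if set(tree.taxa) != set(matrix.taxa):
            raise ValueError("tree tips and matrix taxa differ")
        row_of_tip = np.array([order[t] for t in tree.taxa])
        self.tree = tree
        self.mode = ascertainment
        self.n_categories = n_categories
        self.partitions = list(scheme.mapping)
        cid_index = {cid: i for i, cid in enumerate(matrix.char_id)}
        self._tip_states: dict[str, np.ndarray] = {}
        self._kvec: dict[str, np.ndarray] = {}
        self._work: dict[str, np.ndarray] = {}
        self._n_data: dict[str, int] = {}
        self._const_k: dict[str, np.ndarray] = {}
        for name, ids in scheme.mapping.items():
            cols = np.array([cid_index[c] for c in ids], dtype=np.int64)
            tips = matrix.states[row_of_tip][:, cols]
            kv = matrix.declared_k[cols]
            self._tip_states[name] = tips
            self._n_data[name] = len(ids)
            if ascertainment == CONDITION_ON_VARIABLE:
                # append one constant-pattern column per (distinct k, state):
                # the same pruning pass then yields the correction terms
                tiles, kcol = [], []
                for k in np.unique(kv):
                    for s in range(k):
                        tiles.append(np.full(tree.n_tips, s, dtype=np.int16))
                        kcol.append(k)
                tips = np.hstack([tips, np.array(tiles, dtype=np.int16).T])
                self._const_k[name] = np.array(kcol, dtype=np.int64)
                kv = np.concatenate([kv, self._const_k[name]])
            kv = np.ascontiguousarray(kv)
            self._kvec[name] = kv
            self._work[name] = _tip_partials(tree.n_nodes, tips, kv)
        # correction bookkeeping: per distinct k, the slice of constant
        # columns and the number of data characters with that k
        self._corr: dict[str, list[tuple[int, int, int, int]]] = {}
        if ascertainment == CONDITION_ON_VARIABLE:
            for name in scheme.mapping:
                const_k = self._const_k[name]
                kv = self._kvec[name][: self._n_data[name]]
                rows = []
                pos = 0
                for k in np.unique(const_k):
                    nk = int(k)
                    rows.append((nk, pos, pos + nk, int((kv == k).sum())))
                    pos += nk
                self._corr[name] = rows
        self._gamma_cache: tuple[float, np.ndarray] = (np.nan, np.ones(1))

    def partition_loglik(
        self,
        name: str,
        ages: np.ndarray,
        branch_rates: np.ndarray,
        alpha: float,
    ) -> float:
        """Log-likelihood of one partition at the given ages and rates."""
        dur = self.tree.branch_durations(ages)
        nu = dur * branch_rates
        if self.n_categories == 1:
            rates = self._gamma_cache[1]
        elif alpha == self._gamma_cache[0]:
            rates = self._gamma_cache[1]
        else:
            rates = discrete_gamma_rates(alpha, self.n_categories)
            self._gamma_cache = (alpha, rates)
        ll = _char_logliks(
            self.tree, nu, None, self._kvec[name], rates,
            workspace=self._work[name],
        )
        n_data = self._n_data[name]
        total = float(ll[:n_data].sum())
        if self.mode == CONDITION_ON_VARIABLE:
            pc = np.exp(ll[n_data:])
            for _k, lo, hi, count in self._corr[name]:
                pv = 1.0 - float(pc[lo:hi].sum())
                if pv <= 0:
                    return -np.inf
                total -= count * np.log(pv)
        return total

    def loglik(
        self,
        ages: np.ndarray,
        branch_rates: dict[str, np.ndarray],
        alphas: dict[str, float],
    ) -> tuple[float, dict[str, float]]:
        per = {
            name: self.partition_loglik(name, ages, branch_rates[name], alphas[name])
            for name in self.partitions
        }
        return float(sum(per.values())), per


def matrix_loglik(
    matrix: CharacterMatrix,
    scheme: PartitionScheme,
    tree: TimeTree,
    branch_rates: dict[str, np.ndarray],
    site_models: dict[str, SiteRateModel],
    mode: str = NONE,
) -> tuple[float, dict[str, float]]:
    """Total and per-partition Mk log-likelihood of a matrix.

    ``branch_rates[name]`` gives the per-node parent-edge rates
    (changes/character/Myr) of partition ``name``; ``site_models[name]``
    its gamma shape and category count.
    """
    cats = {sm.n_categories for sm in site_models.values()}
    if len(cats) != 1:
        raise ValueError("all partitions must share the category count")
    engine = MkPartitionedLikelihood(
        matrix, tree, scheme, n_categories=cats.pop(), ascertainment=mode
    )
    alphas = {name: site_models[name].alpha for name in scheme.mapping}
    return engine.loglik(tree.ages, branch_rates, alphas)
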