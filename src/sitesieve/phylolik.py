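"""Likelihood computations on fixed topologies.

Implements Felsenstein pruning with a discrete-Gamma rate mixture over
site-pattern-compressed alignments, coordinate-ascent fitting of branch
lengths and substitution parameters on a fixed topology, per-site
log-likelihood scores (LLS) for competing constrained hypotheses,
maximum-likelihood per-site rate multipliers, gene rate summaries, and
small-scale tree search (exhaustive enumeration or NNI hill climbing).

Branch-length optimization uses the standard outside/inside decomposition:
for one branch, the likelihood as a function of its length reduces to
sums of eigenvalue exponentials against cached partial products, so Brent
iterations cost O(states) per site pattern.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .seqio import Alignment, IUPAC_NT
from .substmodel import AA_STATES, NT_STATES, SubstitutionModel
from .trees import Tree, all_unrooted_topologies

__all__ = [
    "PruningEngine",
    "FitResult",
    "HypothesisSet",
    "SiteLikelihoodMatrix",
    "loglik",
    "fit_on_topology",
    "fit_partitioned",
    "site_lls_for_hypotheses",
    "estimate_site_rates",
    "gene_rate_stats",
    "remove_fast_genes",
    "nj_tree",
    "search_ml_tree",
    "empirical_frequencies",
]

BL_MIN, BL_MAX = 1e-8, 10.0
_TINY = 1e-300

_AA_AMBIG = {"B": "DN", "Z": "EQ", "J": "IL"}


def _char_partials(alphabet: str) -> dict[str, np.ndarray]:
    states = NT_STATES if alphabet == "nt" else AA_STATES
    n = len(states)
    table: dict[str, np.ndarray] = {}
    if alphabet == "nt":
        for ch, resolved in IUPAC_NT.items():
            v = np.zeros(n)
            for r in resolved:
                v[states.index(r)] = 1.0
            table[ch] = v
    else:
        for i, ch in enumerate(states):
            v = np.zeros(n)
            v[i] = 1.0
            table[ch] = v
        for ch, resolved in _AA_AMBIG.items():
            v = np.zeros(n)
            for r in resolved:
                v[states.index(r)] = 1.0
            table[ch] = v
        for ch in "X-?*":
            table[ch] = np.ones(n)
    return table


def _validate_tree(tree: Tree, aln: Alignment) -> None:
    names = tree.leaf_names
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    missing = set(names) - set(aln.taxa)
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    rooted = tree.reroot_at_leaf()
    for n in rooted.postorder():
        if n is rooted.root or n.is_leaf:
            continue
        if len(n.children) != 2:
            raise ValueError("tree is not fully resolved (polytomy found)")


class PruningEngine:
    """Pruning likelihood over the pattern-compressed alignment columns.

    The engine is bound to one alignment/taxon subset and one model; the
    tree may vary between calls, which is what makes topology search and
    per-hypothesis scoring cheap.
    """

    def __init__(self, aln: Alignment, model: SubstitutionModel,
                 taxa: list[str] | None = None):
        if model.alphabet != aln.alphabet:
            raise ValueError("model alphabet does not match alignment")
        self.taxa = list(taxa) if taxa is not None else list(aln.taxa)
        missing = set(self.taxa) - set(aln.taxa)
        if missing:
            raise ValueError(f"taxa absent from alignment: {sorted(missing)}")
        table = _char_partials(aln.alphabet)
        chars = sorted(table)
        lookup = {c: i for i, c in enumerate(chars)}
        part = np.array([table[c] for c in chars])
        rows = [aln.taxa.index(t) for t in self.taxa]
        codes = np.array(
            [[lookup[c] for c in aln.matrix[r]] for r in rows], dtype=np.int16
        )
        uniq, inverse = np.unique(codes.T, axis=0, return_inverse=True)
        self.n_sites = aln.n_sites
        self.pattern_index = inverse
        self.weights = np.bincount(inverse, minlength=len(uniq)).astype(float)
        self.tip = {t: part[uniq[:, j]] for j, t in enumerate(self.taxa)}
        self.n_patterns = len(uniq)
        self.set_model(model)

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.lam, self.u, self.uinv = model.eigensystem()
        self.pi = model.freqs
        self.cat_rates = model.category_rates()

    # -------------------------------------------------------------- core
    def _expand(self, L: np.ndarray, k: int) -> np.ndarray:
        if L.ndim == 2:
            return np.broadcast_to(L, (k,) + L.shape)
        return L

    def _edge_exp(self, t: float, rates: np.ndarray,
                  per_pattern: bool) -> np.ndarray:
        """exp(lam * t * r) with r per category (k,) or per pattern (npat,).

        Returns (k, 1, ns) or (1, npat, ns) respectively."""
        e = np.exp(np.multiply.outer(t * rates, self.lam))
        return e[None, :, :] if per_pattern else e[:, None, :]

    def _passes(self, tree: Tree, rates: np.ndarray, per_pattern: bool):
        """Postorder partials L, parent-bound messages S, and log-scalers."""
        k = 1 if per_pattern else len(rates)
        L: dict[int, np.ndarray] = {}
        S: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        post = tree.postorder()
        for node in post:
            if not node.children:
                if node.name not in self.tip:
                    raise ValueError(f"leaf {node.name!r} not in engine taxa")
                L[id(node)] = self.tip[node.name]
                scale[id(node)] = np.zeros((1, self.n_patterns))
            else:
                prod = None
                sc = np.zeros((1, self.n_patterns))
                for c in node.children:
                    prod = S[id(c)] if prod is None else prod * S[id(c)]
                    sc = sc + scale[id(c)]
                if node.name in self.tip:  # leaf acting as root
                    prod = prod * self.tip[node.name][None, :, :]
                prod = np.clip(prod, 0.0, None)  # eigen roundoff can dip below 0
                m = np.clip(prod.max(axis=2, keepdims=True), _TINY, None)
                prod = prod / m
                sc = sc + np.log(m[..., 0])
                L[id(node)] = prod
                scale[id(node)] = sc
            if node.parent is not None:
                t = node.length if node.length is not None else 0.1
                Lk = self._expand(L[id(node)], k)
                W = Lk @ self.uinv.T
                W = W * self._edge_exp(t, rates, per_pattern)
                S[id(node)] = W @ self.u.T
                scale[id(node)] = np.broadcast_to(
                    scale[id(node)], (W.shape[0], self.n_patterns)
                )
        return post, L, S, scale

    def _root_site_ll(self, tree, L, scale, k: int) -> np.ndarray:
        root = tree.root
        part = self._expand(L[id(root)], k)
        tot = np.clip((part * self.pi[None, None, :]).sum(axis=2), _TINY, None)
        logtot = np.log(tot) + scale[id(root)]
        if logtot.shape[0] == 1:
            return logtot[0]
        return np.logaddexp.reduce(logtot - math.log(k), axis=0)

    def pattern_loglik(self, tree: Tree,
                       pattern_rates: np.ndarray | None = None) -> np.ndarray:
        """Per-pattern log-likelihood; with `pattern_rates`, the Gamma
        mixture is replaced by a fixed rate multiplier per pattern."""
        if pattern_rates is not None:
            rates, per_pattern, k = np.asarray(pattern_rates, float), True, 1
        else:
            rates, per_pattern, k = self.cat_rates, False, len(self.cat_rates)
        _, L, S, scale = self._passes(tree, rates, per_pattern)
        return self._root_site_ll(tree, L, scale, k)

    def site_loglik(self, tree: Tree) -> np.ndarray:
        return self.pattern_loglik(tree)[self.pattern_index]

    def loglik(self, tree: Tree) -> float:
        return float(self.pattern_loglik(tree) @ self.weights)

    # ---------------------------------------------------- branch fitting
    def _outside(self, tree: Tree, rates: np.ndarray):
        """Outside arrays O[v]: pi-weighted likelihood of everything outside
        v's subtree, indexed by the state of v's parent."""
        k = len(rates)
        post, L, S, scale = self._passes(tree, rates, per_pattern=False)
        O: dict[int, np.ndarray] = {}
        oscale: dict[int, np.ndarray] = {}
        zeros = np.zeros((k, self.n_patterns))

        def down_of(node, Ov, osc):
            t = node.length if node.length is not None else 0.1
            A = Ov @ self.u
            A = A * self._edge_exp(t, rates, per_pattern=False)
            return A @ self.uinv, osc

        stack = [tree.root]
        root_base = np.broadcast_to(
            self.pi[None, None, :], (k, self.n_patterns, len(self.pi))
        )
        if tree.root.name in self.tip:
            root_base = root_base * self.tip[tree.root.name][None, :, :]
        down = {id(tree.root): (root_base, zeros)}
        while stack:
            u = stack.pop()
            d, dsc = down[id(u)]
            for c in u.children:
                acc, asc = d, dsc
                for s in u.children:
                    if s is c:
                        continue
                    acc = acc * S[id(s)]
                    asc = asc + scale[id(s)]
                acc = np.clip(acc, 0.0, None)
                m = np.clip(acc.max(axis=2, keepdims=True), _TINY, None)
                acc = acc / m
                asc = asc + np.log(m[..., 0])
                O[id(c)], oscale[id(c)] = acc, asc
                if c.children:
                    down[id(c)] = down_of(c, acc, asc)
                    stack.append(c)
        return post, L, S, scale, O, oscale

    def optimize_branch_lengths(self, tree: Tree, sweeps: int = 3,
                                xatol: float = 1e-5) -> float:
        """In-place Brent optimization of every branch, `sweeps` passes.

        Each one-branch profile is exact at the moment it is optimized:
        below-partials are refreshed bottom-up as the postorder sweep
        advances, and the outside array for the focal branch is rebuilt by
        walking from the root down to it using current messages.  The
        ascent is therefore monotone in the total log-likelihood."""
        rates = self.cat_rates
        k = len(rates)
        logw = -math.log(k)
        post, L, S, scale, _sscale = self._fresh_caches(tree, rates)
        for _ in range(sweeps):
            for v in post:
                if v.parent is None:
                    continue
                if v.children:  # refresh below-partial from children messages
                    self._refresh_partial(v, L, S, scale)
                O, osc = self._walk_outside(tree, v, S, scale, rates, k)
                Lk = self._expand(L[id(v)], k)
                G = (Lk @ self.uinv.T) * (O @ self.u)
                gsc = np.broadcast_to(scale[id(v)], (k, self.n_patterns)) + osc

                def nll(t):
                    e = np.exp(np.multiply.outer(t * rates, self.lam))
                    f = np.clip((G * e[:, None, :]).sum(axis=2), _TINY, None)
                    site = np.logaddexp.reduce(np.log(f) + gsc + logw, axis=0)
                    return -float(site @ self.weights)

                cur = nll(v.length if v.length is not None else 0.1)
                res = minimize_scalar(
                    nll, bounds=(BL_MIN, BL_MAX), method="bounded",
                    options={"xatol": xatol},
                )
                if res.fun < cur:
                    v.length = float(res.x)
                # refresh the parent-bound message with the new length
                t = v.length if v.length is not None else 0.1
                W = self._expand(L[id(v)], k) @ self.uinv.T
                W = W * self._edge_exp(t, rates, per_pattern=False)
                S[id(v)] = W @ self.u.T
        return self.loglik(tree)

    def _fresh_caches(self, tree: Tree, rates: np.ndarray):
        post, L, S, scale = self._passes(tree, rates, per_pattern=False)
        sscale = {
            i: np.broadcast_to(s, (len(rates), self.n_patterns))
            for i, s in scale.items()
        }
        return post, L, S, scale, sscale

    def _refresh_partial(self, v, L, S, scale) -> None:
        prod, sc = None, 0.0
        for c in v.children:
            prod = S[id(c)] if prod is None else prod * S[id(c)]
            sc = sc + scale[id(c)]
        if v.name in self.tip:
            prod = prod * self.tip[v.name][None, :, :]
        prod = np.clip(prod, 0.0, None)
        m = np.clip(prod.max(axis=2, keepdims=True), _TINY, None)
        L[id(v)] = prod / m
        scale[id(v)] = sc + np.log(m[..., 0])

    def _walk_outside(self, tree: Tree, v, S, scale, rates, k: int):
        """Outside array for v's branch via a root-to-v walk over current
        messages (indexed by the state of v's parent, pi included)."""
        path = []
        node = v
        while node is not None:
            path.append(node)
            node = node.parent
        path.reverse()  # root ... parent(v), v
        down = np.broadcast_to(
            self.pi[None, None, :], (1, self.n_patterns, len(self.pi))
        )
        if tree.root.name in self.tip:
            down = down * self.tip[tree.root.name][None, :, :]
        dsc = np.zeros((1, self.n_patterns))
        for a, nxt in zip(path[:-1], path[1:]):
            acc, asc = down, dsc
            for c in a.children:
                if c is nxt:
                    continue
                acc = acc * S[id(c)]
                asc = asc + scale[id(c)]
            acc = np.clip(acc, 0.0, None)
            m = np.clip(acc.max(axis=2, keepdims=True), _TINY, None)
            acc = acc / m
            asc = asc + np.log(m[..., 0])
            if nxt is v:
                return acc, np.broadcast_to(asc, (k, self.n_patterns))
            t = nxt.length if nxt.length is not None else 0.1
            A = acc @ self.u
            A = A * self._edge_exp(t, rates, per_pattern=False)
            down = A @ self.uinv
            dsc = asc
        raise RuntimeError("walk did not reach the focal branch")


# --------------------------------------------------------------- fitting
@dataclass
class FitResult:
    """Fitted branch lengths + substitution model on a fixed topology."""

    tree: Tree
    model: SubstitutionModel
    loglik: float
    site_loglik: np.ndarray
    converged: bool
    n_sweeps: int

    def summary(self) -> str:
        bl = self.tree.branch_lengths()
        lines = [
            "Fixed-topology fit",
            f"  log-likelihood : {self.loglik:.6f}",
            f"  sites          : {len(self.site_loglik)}",
            f"  tree length    : {sum(bl):.4f} over {len(bl)} branches",
            f"  alpha          : {self.model.alpha}",
            f"  converged      : {self.converged} ({self.n_sweeps} sweeps)",
        ]
        return "\n".join(lines)


def empirical_frequencies(aln: Alignment, taxa: list[str] | None = None,
                          pseudocount: float = 1.0) -> np.ndarray:
    states = NT_STATES if aln.alphabet == "nt" else AA_STATES
    rows = (
        aln.matrix
        if taxa is None
        else aln.matrix[[aln.taxa.index(t) for t in taxa]]
    )
    counts = np.array([(rows == s).sum() for s in states], float) + pseudocount
    return counts / counts.sum()


def _pack(model: SubstitutionModel, which: tuple[str, ...]) -> np.ndarray:
    x = []
    if "exchangeabilities" in which:
        s = np.asarray(model.exchangeabilities, float)
        x.extend(np.log(np.clip(s[:-1] / s[-1], 1e-8, 1e8)))
    if "frequencies" in which:
        f = model.freqs
        x.extend(np.log(np.clip(f[:-1] / f[-1], 1e-8, 1e8)))
    if "alpha" in which:
        x.append(math.log(model.alpha if model.alpha else 1.0))
    return np.array(x)


def _unpack(x: np.ndarray, model: SubstitutionModel,
            which: tuple[str, ...]) -> SubstitutionModel:
    i = 0
    exch = np.asarray(model.exchangeabilities, float).copy()
    freqs = model.freqs.copy()
    alpha = model.alpha
    if "exchangeabilities" in which:
        n = len(exch) - 1
        exch = np.concatenate([np.exp(x[i : i + n]), [1.0]])
        i += n
    if "frequencies" in which:
        n = len(freqs) - 1
        raw = np.concatenate([np.exp(x[i : i + n]), [1.0]])
        freqs = raw / raw.sum()
        i += n
    if "alpha" in which:
        alpha = float(np.exp(x[i]))
        i += 1
    return SubstitutionModel(exch, freqs, alpha, model.n_cats, model.alphabet)


def fit_on_topology(
    aln: Alignment,
    topology: Tree,
    model: SubstitutionModel | None = None,
    optimize: tuple[str, ...] = (
        "branch_lengths", "exchangeabilities", "frequencies", "alpha",
    ),
    max_sweeps: int = 100,
    tol: float = 1e-6,
    branch_sweeps: int = 1,
) -> FitResult:
    """Coordinate-ascent ML fit of branch lengths and model parameters on a
    fixed, fully resolved topology.

    Sweeps alternate Brent passes over branches with Nelder-Mead moves on
    the (log-transformed) substitution parameters until the log-likelihood
    improves by less than `tol` or `max_sweeps` is reached.
    """
    _validate_tree(topology, aln)
    tree = topology.copy()
    for e in tree.edges():
        if e.length is None:
            e.length = 0.1
        e.length = float(min(max(e.length, BL_MIN), BL_MAX))
    if model is None:
        freqs = (
            empirical_frequencies(aln, topology.leaf_names)
            if aln.alphabet == "nt"
            else np.full(20, 0.05)
        )
        nex = 6 if aln.alphabet == "nt" else 190
        model = SubstitutionModel(
            np.ones(nex), freqs,
            1.0 if "alpha" in optimize else None, 4, aln.alphabet,
        )
    engine = PruningEngine(aln, model, taxa=tree.leaf_names)
    which = tuple(w for w in optimize if w != "branch_lengths")
    ll = engine.loglik(tree)
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        prev = ll
        if "branch_lengths" in optimize:
            engine.optimize_branch_lengths(tree, sweeps=branch_sweeps)
        if which:
            x0 = _pack(engine.model, which)

            def nll(x):
                try:
                    m = _unpack(x, engine.model, which)
                    engine.set_model(m)
                    return -engine.loglik(tree)
                except (ValueError, np.linalg.LinAlgError):
                    return 1e12

            # modest per-sweep budget; the coordinate-ascent loop iterates
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"maxiter": 30 + 15 * len(x0),
                                    "fatol": max(tol / 10, 1e-4),
                                    "xatol": 1e-4})
            if -res.fun >= -nll(x0):
                engine.set_model(_unpack(res.x, engine.model, which))
            else:
                engine.set_model(_unpack(x0, engine.model, which))
        ll = engine.loglik(tree)
        if ll - prev < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fit_on_topology: no convergence within max_sweeps")
    site_ll = engine.site_loglik(tree)
    return FitResult(tree, engine.model, float(site_ll.sum()), site_ll,
                     converged, sweep)


def _joint_branch_sweep(engines: list[PruningEngine], tree: Tree,
                        xatol: float = 1e-5) -> None:
    """One Brent pass over every branch, maximizing the summed likelihood
    of several engines (gene partitions) sharing the tree."""
    per_engine = []
    for eng in engines:
        rates = eng.cat_rates
        post, L, S, scale = eng._passes(tree, rates, per_pattern=False)
        per_engine.append((eng, rates, post, L, S, scale))
    post0 = per_engine[0][2]
    for vi, v in enumerate(post0):
        if v.parent is None:
            continue
        profiles = []
        for eng, rates, post, L, S, scale in per_engine:
            node = post[vi]
            k = len(rates)
            if node.children:
                eng._refresh_partial(node, L, S, scale)
            O, osc = eng._walk_outside(tree, node, S, scale, rates, k)
            Lk = eng._expand(L[id(node)], k)
            G = (Lk @ eng.uinv.T) * (O @ eng.u)
            gsc = np.broadcast_to(scale[id(node)], (k, eng.n_patterns)) + osc
            profiles.append((eng, rates, k, G, gsc))

        def nll(t):
            total = 0.0
            for eng, rates, k, G, gsc in profiles:
                e = np.exp(np.multiply.outer(t * rates, eng.lam))
                f = np.clip((G * e[:, None, :]).sum(axis=2), _TINY, None)
                site = np.logaddexp.reduce(
                    np.log(f) + gsc - math.log(k), axis=0
                )
                total += float(site @ eng.weights)
            return -total

        cur = nll(v.length if v.length is not None else 0.1)
        res = minimize_scalar(nll, bounds=(BL_MIN, BL_MAX), method="bounded",
                              options={"xatol": xatol})
        if res.fun < cur:
            v.length = float(res.x)
        for eng, rates, post, L, S, scale in per_engine:
            node = post[vi]
            t = v.length if v.length is not None else 0.1
            k = len(rates)
            W = eng._expand(L[id(node)], k) @ eng.uinv.T
            W = W * eng._edge_exp(t, rates, per_pattern=False)
            S[id(node)] = W @ eng.u.T


def fit_partitioned(
    aln: Alignment,
    topology: Tree,
    model_template: SubstitutionModel | None = None,
    optimize: tuple[str, ...] = (
        "branch_lengths", "exchangeabilities", "frequencies", "alpha",
    ),
    max_sweeps: int = 30,
    tol: float = 1e-5,
) -> tuple[Tree, dict[str, SubstitutionModel], float]:
    """Partitioned fit: shared branch lengths, unlinked per-gene
    substitution parameters.

    Branch lengths are optimized against the summed per-gene likelihoods;
    each gene's exchangeabilities/frequencies/shape are then updated on its
    own engine.  Returns (tree, per-gene models, total log-likelihood).
    """
    _validate_tree(topology, aln)
    tree = topology.copy()
    for e in tree.edges():
        e.length = float(min(max(e.length if e.length is not None else 0.1,
                                 BL_MIN), BL_MAX))
    genes = {g: aln.gene_slice(g) for g in aln.partitions}
    engines: dict[str, PruningEngine] = {}
    for g, sub in genes.items():
        if model_template is None:
            freqs = (
                empirical_frequencies(sub, tree.leaf_names)
                if sub.alphabet == "nt" else np.full(20, 0.05)
            )
            nex = 6 if sub.alphabet == "nt" else 190
            m = SubstitutionModel(
                np.ones(nex), freqs,
                1.0 if "alpha" in optimize else None, 4, sub.alphabet,
            )
        else:
            m = SubstitutionModel(
                np.array(model_template.exchangeabilities, float),
                model_template.freqs.copy(), model_template.alpha,
                model_template.n_cats, model_template.alphabet,
            )
        engines[g] = PruningEngine(sub, m, taxa=tree.leaf_names)
    which = tuple(w for w in optimize if w != "branch_lengths")

    def total_ll() -> float:
        return sum(e.loglik(tree) for e in engines.values())

    ll = total_ll()
    for _ in range(max_sweeps):
        prev = ll
        if "branch_lengths" in optimize:
            _joint_branch_sweep(list(engines.values()), tree)
        if which:
            for eng in engines.values():
                x0 = _pack(eng.model, which)

                def nll(x, eng=eng):
                    try:
                        eng.set_model(_unpack(x, eng.model, which))
                        return -eng.loglik(tree)
                    except (ValueError, np.linalg.LinAlgError):
                        return 1e12

                res = minimize(nll, x0, method="Nelder-Mead",
                               options={"maxiter": 30 + 15 * len(x0),
                                        "fatol": max(tol / 10, 1e-4),
                                        "xatol": 1e-4})
                best = res.x if res.fun <= nll(x0) else x0
                eng.set_model(_unpack(best, eng.model, which))
        ll = total_ll()
        if ll - prev < tol:
            break
    models = {g: e.model for g, e in engines.items()}
    return tree, models, float(ll)


# ------------------------------------------------------------ hypotheses
@dataclass
class HypothesisSet:
    """Named, fully resolved constraint topologies for one question."""

    hypotheses: dict[str, Tree]

    def __post_init__(self) -> None:
        if len(self.hypotheses) < 1:
            raise ValueError("empty hypothesis set")
        leafsets = {frozenset(t.leaf_names) for t in self.hypotheses.values()}
        if len(leafsets) != 1:
            raise ValueError("hypothesis trees must share one leaf set")

    @property
    def names(self) -> list[str]:
        return list(self.hypotheses)

    def items(self):
        return self.hypotheses.items()


@dataclass
class SiteLikelihoodMatrix:
    """Sites x hypotheses table of per-site log-likelihood scores."""

    df: pd.DataFrame  # index: 1-based site; columns: hypothesis names

    def __post_init__(self) -> None:
        if not np.isfinite(self.df.to_numpy()).all():
            raise ValueError("non-finite per-site log-likelihoods")

    @property
    def hypothesis_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def total_loglik(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "site", self.df.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteLikelihoodMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("site")
        df.index.name = None
        return cls(df)

    def to_sitelh(self, path) -> None:
        """CONSEL/puzzle-style .sitelh layout: one row per hypothesis."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.df.columns)} {len(self.df)}\n")
            for name in self.df.columns:
                vals = " ".join(f"{v:.6f}" for v in self.df[name])
                fh.write(f"{name} {vals}\n")


def site_lls_for_hypotheses(
    aln: Alignment,
    hypotheses: HypothesisSet,
    model: SubstitutionModel | None = None,
    optimize: tuple[str, ...] = (
        "branch_lengths", "exchangeabilities", "frequencies", "alpha",
    ),
    **fit_kwargs,
) -> tuple[SiteLikelihoodMatrix, dict[str, FitResult]]:
    """Fit every hypothesis topology independently and collect per-site LLS."""
    fits = {
        name: fit_on_topology(aln, tree, model, optimize, **fit_kwargs)
        for name, tree in hypotheses.items()
    }
    df = pd.DataFrame(
        {name: fit.site_loglik for name, fit in fits.items()},
        index=np.arange(1, aln.n_sites + 1),
    )
    df.index.name = None
    return SiteLikelihoodMatrix(df), fits


# ------------------------------------------------------------ site rates
def estimate_site_rates(
    aln: Alignment,
    fits: list[FitResult] | dict[str, FitResult],
    r_max: float = 50.0,
    grid_size: int = 160,
    refine_iter: int = 40,
) -> np.ndarray:
    """ML per-site rate multipliers, averaged across fitted hypotheses.

    For each hypothesis the Gamma mixture is switched off and a single
    multiplier r in [0, r_max] scales every branch; the per-site optimum is
    located on a geometric grid and refined by golden-section search,
    vectorized across site patterns.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    gold = (math.sqrt(5.0) - 1.0) / 2.0
    all_rates = []
    for fit in fits:
        model = SubstitutionModel(
            fit.model.exchangeabilities, fit.model.freqs, None, 1,
            fit.model.alphabet,
        )
        engine = PruningEngine(aln, model, taxa=fit.tree.leaf_names)
        grid = np.concatenate([[0.0], np.geomspace(1e-3, r_max, grid_size)])
        lls = np.stack(
            [
                engine.pattern_loglik(
                    fit.tree, pattern_rates=np.full(engine.n_patterns, r)
                )
                for r in grid
            ]
        )  # (grid, npat)
        best = lls.argmax(axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, len(grid) - 1)]
        a, b = lo.copy(), hi.copy()
        x1 = b - gold * (b - a)
        x2 = a + gold * (b - a)
        f1 = engine.pattern_loglik(fit.tree, pattern_rates=x1)
        f2 = engine.pattern_loglik(fit.tree, pattern_rates=x2)
        for _ in range(refine_iter):
            take1 = f1 >= f2  # maximum lies in the left sub-interval
            b = np.where(take1, x2, b)
            a = np.where(take1, a, x1)
            x1n = b - gold * (b - a)
            x2n = a + gold * (b - a)
            xq = np.where(take1, x1n, x2n)
            fq = engine.pattern_loglik(fit.tree, pattern_rates=xq)
            x1, f1, x2, f2 = (
                np.where(take1, x1n, x2),
                np.where(take1, fq, f2),
                np.where(take1, x1, x2n),
                np.where(take1, f1, fq),
            )
        r_hat = (a + b) / 2.0
        ll_hat = engine.pattern_loglik(fit.tree, pattern_rates=r_hat)
        ll_zero = engine.pattern_loglik(
            fit.tree, pattern_rates=np.zeros(engine.n_patterns)
        )
        r_hat = np.where(ll_zero >= ll_hat - 1e-10, 0.0, r_hat)
        all_rates.append(r_hat[engine.pattern_index])
    return np.mean(all_rates, axis=0)


# ------------------------------------------------------------ gene rates
def gene_rate_stats(tree: Tree) -> dict[str, float]:
    """Tree length and mean branch length over all branches."""
    edges = tree.edges()
    lengths = [e.length for e in edges]
    if any(l is None for l in lengths):
        raise ValueError("tree has branches without lengths")
    total = float(sum(lengths))
    return {
        "tree_length": total,
        "mean_branch_length": total / len(lengths),
        "n_branches": len(lengths),
    }


def remove_fast_genes(
    mean_lengths: dict,
    fraction: float | None = None,
    cutoff: float | None = None,
) -> tuple[list[str], list[str]]:
    """Partition genes into (retained, removed) by mean branch length.

    Accepts gene -> mean branch length, or gene -> fitted tree (the mean is
    then computed here).  With `fraction`, the ceil(fraction*N) fastest
    genes are removed; with `cutoff`, all genes whose mean branch length
    exceeds it.
    """
    if (fraction is None) == (cutoff is None):
        raise ValueError("give exactly one of fraction or cutoff")
    mean_lengths = {
        g: (gene_rate_stats(v)["mean_branch_length"] if isinstance(v, Tree) else v)
        for g, v in mean_lengths.items()
    }
    ranked = sorted(mean_lengths, key=lambda g: (-mean_lengths[g], g))
    if fraction is not None:
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        k = math.ceil(fraction * len(ranked))
    else:
        k = sum(1 for g in ranked if mean_lengths[g] > cutoff)
    removed = ranked[:k]
    retained = [g for g in mean_lengths if g not in set(removed)]
    return retained, removed


# ------------------------------------------------------------ tree search
def _pairwise_jc_distance(aln: Alignment, taxa: list[str]) -> np.ndarray:
    miss = aln.missing_chars
    rows = [aln.matrix[aln.taxa.index(t)] for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    states = frozenset(NT_STATES if aln.alphabet == "nt" else AA_STATES)
    cap = 0.749 if aln.alphabet == "nt" else 0.94
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.array(
                [a in states and b in states for a, b in zip(rows[i], rows[j])]
            )
            if ok.sum() == 0:
                p = cap
            else:
                p = min(float((rows[i][ok] != rows[j][ok]).mean()), cap)
            if aln.alphabet == "nt":
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                dist = -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)
            d[i, j] = d[j, i] = max(dist, 0.0)
    return d


def nj_tree(aln: Alignment, taxa: list[str] | None = None) -> Tree:
    """Neighbor-joining starting tree from JC-corrected distances."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    d = _pairwise_jc_distance(aln, taxa)
    header = "," + ",".join(taxa)
    lines = [header]
    for i, t in enumerate(taxa):
        lines.append(t + "," + ",".join(f"{x:.10f}" for x in d[i]))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO("\n".join(lines)), delimiter=","
    )
    nwk = pdm.nj_tree().as_string(schema="newick", suppress_rooting=True)
    tree = Tree.from_newick(nwk)
    for e in tree.edges():
        if e.length is None or e.length < BL_MIN:
            e.length = BL_MIN
    return tree


def search_ml_tree(
    aln: Alignment,
    model: SubstitutionModel | None = None,
    strategy: str = "nni",
    start: Tree | None = None,
    fit_model: bool = True,
    model_optimize: tuple[str, ...] = ("exchangeabilities", "frequencies", "alpha"),
    candidate_sweeps: int = 2,
    max_rounds: int = 50,
) -> tuple[Tree, float]:
    """Maximum-likelihood topology search.

    `exhaustive` enumerates all unrooted binary topologies (only feasible
    for <= 8 taxa); `nni` hill-climbs from a starting tree (NJ by default),
    accepting the best nearest-neighbor interchange until none improves.
    Substitution parameters are fitted once on the starting tree and then
    held fixed while topologies are compared on optimized branch lengths.
    """
    taxa = list(aln.taxa)
    if strategy == "exhaustive" and len(taxa) > 8:
        raise ValueError(
            "exhaustive search supports at most 8 taxa; use strategy='nni'"
        )
    if start is None:
        start = (
            nj_tree(aln, taxa)
            if len(taxa) > 3 or strategy == "nni"
            else all_unrooted_topologies(taxa)[0]
        )
    if model is None or fit_model:
        fit = fit_on_topology(
            aln, start, model,
            optimize=("branch_lengths",)
            + (model_optimize if (fit_model or model is None) else ()),
            max_sweeps=20, tol=1e-4,
        )
        model, start = fit.model, fit.tree
    engine = PruningEngine(aln, model, taxa=taxa)

    def score(tree: Tree, sweeps: int) -> float:
        return engine.optimize_branch_lengths(tree, sweeps=sweeps)

    if strategy == "exhaustive":
        best_tree, best_ll = None, -np.inf
        for topo in all_unrooted_topologies(taxa, default_length=0.1):
            ll = score(topo, sweeps=max(candidate_sweeps, 2))
            if ll > best_ll:
                best_tree, best_ll = topo, ll
        return best_tree, float(best_ll)
    if strategy != "nni":
        raise ValueError(f"unknown strategy {strategy!r}")

    current = start.copy()
    current_ll = score(current, sweeps=3)
    for _ in range(max_rounds):
        improved = False
        best_nb, best_ll = None, current_ll
        for nb in current.nni_neighbors():
            ll = score(nb, sweeps=candidate_sweeps)
            if ll > best_ll + 1e-6:
                best_nb, best_ll = nb, ll
        if best_nb is not None:
            current, current_ll = best_nb, score(best_nb, sweeps=2)
            improved = True
        if not improved:
            break
    return current, float(current_ll)


def loglik(aln: Alignment, tree: Tree, model: SubstitutionModel):
    """Total and per-site log-likelihood of `aln` on `tree` under `model`."""
    _validate_tree(tree, aln)
    engine = PruningEngine(aln, model, taxa=tree.leaf_names)
    site = engine.site_loglik(tree)
    return float(site.sum()), site
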