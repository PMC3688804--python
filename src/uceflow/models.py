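"""Per-locus substitution-model selection by AICc.

Candidate models are JC69, K80, HKY85 and GTR, each with or without
4-category discrete-gamma rate variation (8 candidates).  For each locus a
neighbor-joining guide tree is built from Jukes-Cantor distances, branch
lengths are optimized by per-branch scalar search and substitution
parameters by bounded numerical search, and the winner minimizes
AICc = -2 lnL + 2K + 2K(K+1)/(n-K-1), where K counts substitution free
parameters (base frequencies included for HKY85/GTR, in the MrAIC
convention) plus 2T-3 branch lengths and n is the number of alignment
columns.  Loci for which no candidate leaves n-K-1 > 0 are reported
``too_short`` rather than fitted.

The guide-tree topology stays fixed during fitting: the goal is model
choice, not tree search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import Node, nj_tree

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}

MODEL_NAMES = ("JC69", "K80", "HKY85", "GTR")
#: substitution free-parameter counts, frequencies included where estimated
_SUB_PARAMS = {"JC69": 0, "K80": 1, "HKY85": 4, "GTR": 8}


class SaturationError(ValueError):
    pass


class LikelihoodError(ValueError):
    pass


@dataclass
class ModelFit:
    locus_id: str
    model: str               # e.g. "HKY85+G"
    lnL: float
    K: int
    n: int
    aicc: float
    status: str = "ok"       # ok | too_short
    params: dict | None = None
    tree: Node | None = None


# ---------------------------------------------------------------------------
# Distances


def jc_distance(seq_i: str, seq_j: str, cap: bool = False) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) over shared sites.

    Sites where either sequence is a gap or ambiguity are skipped.  At
    p >= 0.75 the formula diverges; by default that raises
    :class:`SaturationError`, with ``cap=True`` p is clamped just below the
    boundary instead.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences differ in length")
    shared = mismatch = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        if a in _NUC_INDEX and b in _NUC_INDEX:
            shared += 1
            mismatch += a != b
    if shared == 0:
        raise ValueError("no comparable sites")
    p = mismatch / shared
    if p >= 0.75:
        if not cap:
            raise SaturationError(
                f"mismatch fraction {p:.3f} >= 0.75 saturates the JC formula")
        p = 0.7499
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(aln: dict[str, str], cap: bool = True
                       ) -> tuple[list[str], np.ndarray]:
    names = list(aln)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(aln[names[i]], aln[names[j]],
                                            cap=cap)
    return names, d


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities


def empirical_freqs(aln: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for seq in aln.values():
        for c in seq.upper():
            idx = _NUC_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = counts / counts.sum()
    return np.clip(freqs, 1e-6, None) / np.clip(freqs, 1e-6, None).sum()


def rate_matrix(model: str, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Build the normalized reversible rate matrix Q and its frequencies.

    ``params`` may carry ``kappa`` (K80/HKY85), ``rates`` (GTR: the six
    exchangeabilities AC, AG, AT, CG, CT, GT with GT fixed to 1) and
    ``freqs``.  Q is scaled to one expected substitution per unit time.
    """
    base = model.split("+")[0]
    if base in ("JC69", "K80"):
        freqs = np.full(4, 0.25)
    else:
        freqs = np.asarray(params.get("freqs", np.full(4, 0.25)), dtype=float)
    if base == "JC69":
        ex = np.ones(6)
    elif base in ("K80", "HKY85"):
        kappa = float(params.get("kappa", 2.0))
        # exchangeabilities ordered AC, AG, AT, CG, CT, GT
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    elif base == "GTR":
        rates = np.asarray(params.get("rates", np.ones(5)), dtype=float)
        ex = np.concatenate([rates, [1.0]])
    else:
        raise ValueError(f"unknown model {model!r}")
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(ex, pairs):
        Q[i, j] = rate * freqs[j]
        Q[j, i] = rate * freqs[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    if scale <= 0:
        raise LikelihoodError("degenerate rate matrix")
    return Q / scale, freqs


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete gamma categories."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    quantiles = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha,
                               scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], quantiles * alpha, [np.inf]])
    cum = gammainc(alpha + 1.0, bounds)      # E[X 1{X<q}] / E[X], mean 1
    return ncat * np.diff(cum)


class _TransitionCache:
    """Eigendecomposition-backed P(t) for one reversible Q."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        sqrt_pi = np.sqrt(freqs)
        sym = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        self._left = eigvec / sqrt_pi[:, None]
        self._right = (eigvec * sqrt_pi[:, None]).T
        self._eigval = eigval

    def P(self, t: float | np.ndarray) -> np.ndarray:
        """P(t); a vector ``t`` yields a stacked (len(t), 4, 4) array."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise LikelihoodError(f"negative branch length {t}")
        expd = np.exp(np.multiply.outer(t, self._eigval))
        P = (self._left * expd[..., None, :]) @ self._right
        return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Felsenstein pruning


def _encode(aln: dict[str, str]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Compress columns into unique site patterns with weights.

    Gaps and ambiguity codes become missing data (uniform partial
    likelihood).
    """
    names = list(aln)
    length = len(next(iter(aln.values())))
    mat = np.full((len(names), length), 4, dtype=np.int8)
    for r, name in enumerate(names):
        for c, ch in enumerate(aln[name].upper()):
            mat[r, c] = _NUC_INDEX.get(ch, 4)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    leaf_partials: dict[str, np.ndarray] = {}
    eye5 = np.vstack([np.eye(4), np.ones(4)])
    for r, name in enumerate(names):
        leaf_partials[name] = eye5[patterns[r]]
    return leaf_partials, weights.astype(float)


class LikelihoodEngine:
    """Pruning likelihood over one alignment, encoded to site patterns once.

    Re-evaluating the likelihood during branch-length and parameter
    optimization dominates model selection, so the pattern compression is
    hoisted here and rate categories are evaluated as one stacked array.
    """

    def __init__(self, aln: dict[str, str]):
        self.leaf_partials, self.weights = _encode(aln)
        self.taxa = set(aln)
        self.n_sites = int(self.weights.sum())

    def lnL(self, tree: Node, model: str, params: dict | None = None) -> float:
        params = params or {}
        missing = {n.name for n in tree.leaves()} - self.taxa
        if missing:
            raise LikelihoodError(
                f"tree leaves missing from alignment: {missing}")
        Q, freqs = rate_matrix(model, params)
        cache = _TransitionCache(Q, freqs)
        if "+G" in model:
            rates = gamma_category_rates(float(params.get("alpha", 0.5)))
        else:
            rates = np.array([1.0])
        root = self._partial(tree, cache, rates)      # (ncat, npat, 4)
        site_lik = (root @ freqs).mean(axis=0)
        if np.any(site_lik <= 0.0) or not np.all(np.isfinite(site_lik)):
            bad = int(np.argmin(site_lik))
            raise LikelihoodError(
                f"non-finite site likelihood at pattern {bad}")
        return float(self.weights @ np.log(site_lik))

    def _partial(self, node: Node, cache: _TransitionCache,
                 rates: np.ndarray) -> np.ndarray:
        if node.is_leaf:
            leaf = self.leaf_partials[node.name]
            return np.broadcast_to(leaf, (len(rates),) + leaf.shape)
        result = None
        for child in node.children:
            P = cache.P(child.length * rates)         # (ncat, 4, 4)
            below = self._partial(child, cache, rates)
            contrib = np.einsum("cpj,cij->cpi", below, P)
            result = contrib if result is None else result * contrib
        return result


def pruning_lnL(aln: dict[str, str], tree: Node, model: str,
                params: dict | None = None) -> float:
    """Log-likelihood of an alignment on a tree by Felsenstein pruning.

    ``model`` is one of JC69/K80/HKY85/GTR with an optional ``+G`` suffix
    for 4-category discrete-gamma rates (shape ``params['alpha']``).
    Gaps and ambiguities contribute partial likelihood 1 (missing data).
    """
    return LikelihoodEngine(aln).lnL(tree, model, params)


# ---------------------------------------------------------------------------
# Fitting and AICc


def aicc(lnL: float, K: int, n: int) -> float:
    if n - K - 1 <= 0:
        return math.inf
    return -2.0 * lnL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _model_param_count(model: str, n_taxa: int) -> int:
    base = model.split("+")[0]
    K = _SUB_PARAMS[base] + (2 * n_taxa - 3)
    if "+G" in model:
        K += 1
    return K


def _branch_nodes(tree: Node) -> list[Node]:
    return [n for n in tree.postorder() if n is not tree]


def _optimize_branches(engine: LikelihoodEngine, tree, model, params,
                       rounds: int = 1) -> float:
    best = engine.lnL(tree, model, params)
    for _ in range(rounds):
        for node in _branch_nodes(tree):
            original = node.length

            def neg(t: float, node=node) -> float:
                node.length = t
                return -engine.lnL(tree, model, params)

            res = optimize.minimize_scalar(neg, bounds=(1e-8, 10.0),
                                           method="bounded",
                                           options={"xatol": 3e-4,
                                                    "maxiter": 24})
            if -res.fun >= best:
                node.length = float(res.x)
                best = -res.fun
            else:
                node.length = original
    return best


def _optimize_params(engine: LikelihoodEngine, tree, model, params) -> float:
    base = model.split("+")[0]
    keys: list[tuple[str, int]] = []
    x0: list[float] = []
    if base in ("K80", "HKY85"):
        keys.append(("kappa", 0))
        x0.append(math.log(params.get("kappa", 2.0)))
    if base == "GTR":
        rates = params.get("rates", np.ones(5))
        for i in range(5):
            keys.append(("rates", i))
            x0.append(math.log(max(rates[i], 1e-4)))
    if "+G" in model:
        keys.append(("alpha", 0))
        x0.append(math.log(params.get("alpha", 0.5)))
    if not keys:
        return engine.lnL(tree, model, params)

    def apply(x: np.ndarray) -> dict:
        p = dict(params)
        rates = np.array(p.get("rates", np.ones(5)), dtype=float)
        for (key, idx), val in zip(keys, x):
            v = math.exp(min(max(val, -7.0), 7.0))
            if key == "rates":
                rates[idx] = v
            else:
                p[key] = v
        if base == "GTR":
            p["rates"] = rates
        return p

    def neg(x: np.ndarray) -> float:
        try:
            return -engine.lnL(tree, model, apply(x))
        except LikelihoodError:
            return 1e12

    res = optimize.minimize(neg, np.array(x0), method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-3,
                                     "maxiter": 60 * len(x0)})
    params.update(apply(res.x))
    return -neg(res.x)


def fit_models(locus_id: str, aln: dict[str, str],
               candidates: tuple[str, ...] | None = None,
               guide_tree: Node | None = None,
               gamma: bool = True) -> tuple[list[ModelFit], ModelFit | None]:
    """Fit all candidate models to one locus and pick the AICc winner."""
    if len(aln) < 3:
        raise ValueError("model fitting needs >= 3 taxa")
    if candidates is None:
        candidates = tuple(
            m + suffix for m in MODEL_NAMES
            for suffix in (("", "+G") if gamma else ("",)))
    n = len(next(iter(aln.values())))
    n_taxa = len(aln)
    feasible = [m for m in candidates
                if n - _model_param_count(m, n_taxa) - 1 > 0]
    if not feasible:
        fit = ModelFit(locus_id, "", float("nan"),
                       _model_param_count(candidates[0], n_taxa), n,
                       math.inf, status="too_short")
        return [fit], None

    names, dmat = jc_distance_matrix(aln, cap=True)
    base_tree = guide_tree or nj_tree(names, dmat)
    freqs = empirical_freqs(aln)
    engine = LikelihoodEngine(aln)
    fits: list[ModelFit] = []
    # fit plain models first so +G variants start warm from their results
    ordered = sorted(feasible, key=lambda m: ("+G" in m, m))
    done: dict[str, ModelFit] = {}
    for model in ordered:
        base_fit = done.get(model.replace("+G", ""))
        if "+G" in model and base_fit is not None:
            tree = base_fit.tree.copy()
            params = dict(base_fit.params or {})
            params.setdefault("alpha", 0.5)
        else:
            tree = base_tree.copy()
            params = {}
        for node in _branch_nodes(tree):
            node.length = max(node.length, 1e-6)
        if model.split("+")[0] in ("HKY85", "GTR"):
            params["freqs"] = freqs
        lnL = _optimize_branches(engine, tree, model, params, rounds=1)
        has_free = (model.split("+")[0] != "JC69") or ("+G" in model)
        if has_free:
            _optimize_params(engine, tree, model, params)
            lnL = _optimize_branches(engine, tree, model, params, rounds=1)
            lnL = max(lnL, _optimize_params(engine, tree, model, params))
        K = _model_param_count(model, n_taxa)
        fit = ModelFit(locus_id, model, lnL, K, n, aicc(lnL, K, n),
                       params=params, tree=tree)
        done[model] = fit
        fits.append(fit)
    fits.sort(key=lambda f: f.model)
    best = min(fits, key=lambda f: (f.aicc, f.model))
    return fits, best


def group_partitions(best_fits: list[ModelFit]
                     ) -> tuple[dict[str, list[str]], dict[str, str], list[str]]:
    """Group loci sharing a best model into named partitions.

    Returns (partition -> locus ids, partition -> model, excluded locus ids
    for too_short fits).  Partition names derive from the model
    deterministically.
    """
    partitions: dict[str, list[str]] = {}
    models: dict[str, str] = {}
    excluded: list[str] = []
    for fit in best_fits:
        if fit.status != "ok":
            excluded.append(fit.locus_id)
            continue
        name = "p_" + fit.model.replace("+", "_")
        partitions.setdefault(name, []).append(fit.locus_id)
        models[name] = fit.model
    for name in partitions:
        partitions[name].sort()
    return (dict(sorted(partitions.items())),
            dict(sorted(models.items())), sorted(excluded))


def model_distance_matrix(aln: dict[str, str], model: str = "JC69",
                          params: dict | None = None
                          ) -> tuple[list[str], np.ndarray]:
    """Pairwise ML distances under a fitted model (JC closed form shortcut).

    Used by the bootstrap's internal gene-tree estimator: NJ on best-model
    distances.
    """
    if model.split("+")[0] == "JC69" and "+G" not in model:
        return jc_distance_matrix(aln, cap=True)
    params = params or {}
    names = list(aln)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = {"A": aln[names[i]], "B": aln[names[j]]}
            engine = LikelihoodEngine(pair)
            jc0 = jc_distance(aln[names[i]], aln[names[j]], cap=True)

            def neg(t: float) -> float:
                tree = Node(children=[Node("A", t / 2), Node("B", t / 2)])
                return -engine.lnL(tree, model, params)

            res = optimize.minimize_scalar(neg, bounds=(1e-8, 10.0),
                                           method="bounded",
                                           options={"xatol": 1e-5})
            est = float(res.x)
            if neg(est) > neg(max(jc0, 1e-8)):
                est = max(jc0, 1e-8)
            d[i, j] = d[j, i] = est
    return names, d
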