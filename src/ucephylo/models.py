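"""Nucleotide substitution models: pruning likelihoods, model-corrected
pairwise distances, per-locus AICc model selection and partition grouping.

The candidate set is the nested hierarchy JC69 < K80 < F81/HKY85 < GTR,
each with an optional 4-category discrete-gamma rate mixture (+G4, mean
category discretisation), ten models in all. Base frequencies for
F81/HKY85/GTR are empirical; kappa, GTR exchangeabilities and the gamma
shape are optimised by maximum likelihood on a fixed NJ topology with
coordinate-wise branch-length optimisation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._seq import encode
from .matrix import LocusAlignment
from .trees import Clade, DistanceMatrix, nj_clade

log = logging.getLogger(__name__)

# free parameter counts, excluding branch lengths and the +G4 shape
_K_FREE = {"JC69": 0, "K80": 1, "F81": 3, "HKY85": 4, "GTR": 8}

MODEL_NAMES = ["JC69", "JC69+G4", "K80", "K80+G4", "F81", "F81+G4",
               "HKY85", "HKY85+G4", "GTR", "GTR+G4"]

_TRANSITIONS = ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T


class TooFewTaxaError(ValueError):
    """Locus has fewer than 4 taxa with data; model selection is skipped."""


class NoSharedSitesError(ValueError):
    """A sequence pair shares no non-missing columns."""


@dataclass
class SubstitutionModel:
    """A reversible nucleotide model. ``rates`` are the six GTR
    exchangeabilities in order AC, AG, AT, CG, CT, GT (GT fixed at 1)."""

    name: str
    freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    rates: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: Optional[float] = None  # gamma shape; set iff +G4

    def __post_init__(self) -> None:
        base, _, suffix = self.name.partition("+")
        if base not in _K_FREE:
            raise ValueError(f"unknown model {self.name!r}")
        if suffix not in ("", "G4"):
            raise ValueError(f"unknown model suffix {suffix!r}")
        if self.gamma and self.alpha is None:
            self.alpha = 1.0
        if not self.gamma:
            self.alpha = None
        if abs(sum(self.freqs) - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")
        if any(r <= 0 for r in self.rates):
            raise ValueError("exchangeabilities must be > 0")

    @property
    def base_name(self) -> str:
        return self.name.partition("+")[0]

    @property
    def gamma(self) -> bool:
        return self.name.endswith("+G4")

    @property
    def k_free(self) -> int:
        return _K_FREE[self.base_name] + (1 if self.gamma else 0)

    def exchangeabilities(self) -> np.ndarray:
        base = self.base_name
        if base in ("JC69", "F81"):
            return np.ones(6)
        if base in ("K80", "HKY85"):
            return np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        return np.asarray(self.rates, dtype=float)

    def effective_freqs(self) -> np.ndarray:
        if self.base_name in ("JC69", "K80"):
            return np.full(4, 0.25)
        return np.asarray(self.freqs, dtype=float)


@dataclass
class ModelFit:
    locus_id: str
    model: SubstitutionModel
    lnL: float
    aicc: float
    n_sites: int
    k: int  # total free parameters including branch lengths
    used_aic_fallback: bool = False


# ---------------------------------------------------------------------------
# rate matrix machinery
# ---------------------------------------------------------------------------

def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """GTR-family Q, scaled to one expected substitution per unit time."""
    pi = model.effective_freqs()
    s = model.exchangeabilities()
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    Q = np.zeros((4, 4))
    for (i, j), x in zip(pairs, s):
        Q[i, j] = x * pi[j]
        Q[j, i] = x * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def _eigensystem(model: SubstitutionModel):
    Q = rate_matrix(model)
    pi = model.effective_freqs()
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    return w, U, sq


def transition_matrix(model_or_eig, t: float) -> np.ndarray:
    eig = (_eigensystem(model_or_eig)
           if isinstance(model_or_eig, SubstitutionModel) else model_or_eig)
    w, U, sq = eig
    M = (U * np.exp(w * t)) @ U.T
    P = (M / sq[:, None]) * sq[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean-category discretisation of a mean-1 gamma rate distribution."""
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, ncat + 1),
                            a=alpha, scale=1.0 / alpha)
    gi = gammainc(alpha + 1.0, np.where(np.isinf(edges), np.inf,
                                        edges * alpha))
    gi[-1] = 1.0
    return np.diff(gi) * ncat


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Felsenstein pruning on a fixed (rooted or pseudo-rooted) topology,
    with pattern compression. Branch lengths are mutable for optimisation."""

    def __init__(self, aln: LocusAlignment, topology: Clade):
        if aln.length == 0:
            raise ValueError("zero-length alignment")
        taxa = topology.leaves()
        missing = [t for t in taxa if t not in aln.sequences]
        if missing:
            raise ValueError(f"tree tips not in alignment: {missing}")
        arr = np.vstack([encode(aln.sequences[t]) for t in taxa])
        patterns, counts = np.unique(arr, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_sites = aln.length
        self.n_patterns = patterns.shape[1]

        # flatten the clade into postorder arrays
        self.children: List[List[int]] = []
        self.lengths: List[float] = []
        self.leaf_partials: Dict[int, np.ndarray] = {}
        order: List[Tuple[Clade, float]] = []

        def collect(node: Clade, bl: float) -> int:
            kids = [collect(c, w) for c, w in node.children]
            idx = len(order)
            order.append((node, bl))
            self.children.append(kids)
            self.lengths.append(bl)
            if node.is_leaf():
                row = patterns[taxa.index(node.label)]
                part = np.zeros((self.n_patterns, 4))
                ok = row < 4
                part[ok, row[ok]] = 1.0
                part[~ok, :] = 1.0  # missing: uninformative
                self.leaf_partials[idx] = part
            return idx

        self.root = collect(topology, 0.0)
        self.n_edges = len(order) - 1  # root has no edge

    def log_likelihood(self, model: SubstitutionModel) -> float:
        eig = _eigensystem(model)
        pi = model.effective_freqs()
        if model.gamma:
            cat_rates = discrete_gamma_rates(model.alpha)
        else:
            cat_rates = np.array([1.0])
        site_lik = np.zeros(self.n_patterns)
        for rate in cat_rates:
            partial: Dict[int, np.ndarray] = {}
            for idx in range(len(self.children)):
                if idx in self.leaf_partials:
                    partial[idx] = self.leaf_partials[idx]
                    continue
                prod = np.ones((self.n_patterns, 4))
                for c in self.children[idx]:
                    P = transition_matrix(eig, max(self.lengths[c], 0.0) * rate)
                    prod *= partial.pop(c) @ P.T
                partial[idx] = prod
            site_lik += (partial[self.root] @ pi) / len(cat_rates)
        if (site_lik <= 0).any():
            return -np.inf
        return float(self.counts @ np.log(site_lik))

    # -- optimisation -------------------------------------------------------

    def _inside_partials(self, eig, cat_rates) -> Dict[int, np.ndarray]:
        """Inside (subtree) partials per node, shape (ncat, npat, 4)."""
        ncat = len(cat_rates)
        inside: Dict[int, np.ndarray] = {}
        for idx in range(len(self.children)):
            if idx in self.leaf_partials:
                inside[idx] = np.broadcast_to(
                    self.leaf_partials[idx], (ncat, self.n_patterns, 4))
                continue
            prod = np.ones((ncat, self.n_patterns, 4))
            for c in self.children[idx]:
                prod *= self._edge_message(inside[c], self.lengths[c],
                                           eig, cat_rates)
            inside[idx] = prod
        return inside

    @staticmethod
    def _edge_message(inside_child: np.ndarray, t: float, eig,
                      cat_rates) -> np.ndarray:
        """K_c(x) = sum_y P_xy(rate*t) inside_child(y), per category."""
        out = np.empty_like(inside_child)
        for k, rate in enumerate(cat_rates):
            P = transition_matrix(eig, max(t, 0.0) * rate)
            out[k] = inside_child[k] @ P.T
        return out

    def optimize_branch_lengths(self, model: SubstitutionModel,
                                sweeps: int = 2, tol: float = 1e-4) -> float:
        """Coordinate-wise line search over branch lengths using cached
        inside/outside partials (each candidate length is O(patterns)).
        Stops early when a full sweep improves lnL by less than ``tol``;
        a sweep that fails to improve is rolled back."""
        eig = _eigensystem(model)
        pi = model.effective_freqs()
        cat_rates = (discrete_gamma_rates(model.alpha) if model.gamma
                     else np.array([1.0]))
        ncat = len(cat_rates)
        current = self.log_likelihood(model)

        def optimize_edge(c: int, B: np.ndarray, inside_c: np.ndarray):
            def neg(t: float) -> float:
                K = self._edge_message(inside_c, t, eig, cat_rates)
                site = np.einsum("kpx,kpx->p", B, K) / ncat
                if (site <= 0).any():
                    return np.inf
                return -float(self.counts @ np.log(site))

            res = minimize_scalar(neg, bounds=(1e-9, 10.0),
                                  method="bounded",
                                  options={"xatol": 1e-4})
            if res.fun < neg(self.lengths[c]):
                self.lengths[c] = float(res.x)

        def descend(p: int, A: np.ndarray, inside: Dict[int, np.ndarray]):
            kids = self.children[p]
            K = {c: self._edge_message(inside[c], self.lengths[c],
                                       eig, cat_rates) for c in kids}
            for c in kids:
                B = A.copy()
                for s in kids:
                    if s is not c:
                        B *= K[s]
                optimize_edge(c, B, inside[c])
                K[c] = self._edge_message(inside[c], self.lengths[c],
                                          eig, cat_rates)
            for c in kids:
                if c in self.leaf_partials:
                    continue
                B = A.copy()
                for s in kids:
                    if s is not c:
                        B *= K[s]
                A_c = np.empty_like(B)
                for k, rate in enumerate(cat_rates):
                    P = transition_matrix(eig, self.lengths[c] * rate)
                    A_c[k] = B[k] @ P
                descend(c, A_c, inside)

        for _ in range(sweeps):
            saved = list(self.lengths)
            inside = self._inside_partials(eig, cat_rates)
            A_root = np.broadcast_to(pi, (ncat, self.n_patterns, 4)).copy()
            descend(self.root, A_root, inside)
            new = self.log_likelihood(model)
            if new < current:  # staleness safeguard: roll back
                self.lengths = saved
                break
            if new - current < tol:
                current = new
                break
            current = new
        return current


def log_likelihood(aln: LocusAlignment, tree, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of ``aln`` on ``tree`` (dendropy Tree or
    Clade) under ``model``. Missing states contribute partial likelihood 1."""
    from .trees import dendropy_to_clade
    import dendropy

    topo = dendropy_to_clade(tree) if isinstance(tree, dendropy.Tree) else tree
    return TreeLikelihood(aln, topo).log_likelihood(model)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

_FALLBACK_WARNED = set()


def pairwise_distance(seq_i: str, seq_j: str, model: str = "JC69",
                      max_distance: float = 5.0) -> float:
    """Model-corrected distance in substitutions/site. HKY85/GTR fall back
    to JC69 (no closed form) with a logged notice; saturated pairs are
    capped at ``max_distance``."""
    a, b = encode(seq_i), encode(seq_j)
    if a.shape != b.shape:
        raise ValueError("sequences have different lengths")
    shared = (a < 4) & (b < 4)
    n = int(shared.sum())
    if n == 0:
        raise NoSharedSitesError("no shared non-missing columns")
    if model in ("HKY85", "GTR"):
        if model not in _FALLBACK_WARNED:
            _FALLBACK_WARNED.add(model)
            log.info("no closed-form distance for %s; using JC69", model)
        model = "JC69"
    ai, bi = a[shared], b[shared]
    diff = ai != bi
    if model == "JC69":
        p = diff.mean()
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return max_distance
        return min(-0.75 * np.log(arg), max_distance)
    if model == "K80":
        ts = (diff & (((ai == 0) & (bi == 2)) | ((ai == 2) & (bi == 0)) |
                      ((ai == 1) & (bi == 3)) | ((ai == 3) & (bi == 1))))
        P = ts.mean()
        Q = diff.mean() - P
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return max_distance
        return min(-0.5 * np.log(a1) - 0.25 * np.log(a2), max_distance)
    raise ValueError(f"no distance formula for model {model!r}")


def codes_jc_matrix(arr: np.ndarray, max_distance: float = 5.0
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised JC69 distance matrix from an (n_taxa, n_sites) uint8 code
    array. Returns (D, mask) where mask marks pairs with no shared data."""
    valid = (arr < 4).astype(np.float32)
    nshared = np.rint(valid @ valid.T).astype(np.int64)
    nsame = np.zeros_like(nshared)
    for s in range(4):
        one = (arr == s).astype(np.float32)
        nsame += np.rint(one @ one.T).astype(np.int64)
    ndiff = nshared - nsame
    mask = nshared == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nshared > 0, ndiff / np.maximum(nshared, 1), 0.0)
        arg = 1.0 - 4.0 * p / 3.0
        D = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)),
                     max_distance)
    D = np.minimum(D, max_distance)
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(mask, False)
    return D, mask


def distance_matrix(aln: LocusAlignment, model: str = "JC69",
                    max_distance: float = 5.0) -> DistanceMatrix:
    taxa = aln.taxa
    if model in ("JC69", "HKY85", "GTR"):
        arr = np.vstack([encode(aln.sequences[t]) for t in taxa])
        D, mask = codes_jc_matrix(arr, max_distance)
        return DistanceMatrix(taxa, D, mask)
    n = len(taxa)
    D = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pairwise_distance(aln.sequences[taxa[i]],
                                      aln.sequences[taxa[j]],
                                      model=model, max_distance=max_distance)
                D[i, j] = D[j, i] = d
            except NoSharedSitesError:
                mask[i, j] = mask[j, i] = True
    return DistanceMatrix(taxa, D, mask)


# ---------------------------------------------------------------------------
# AICc model selection
# ---------------------------------------------------------------------------

def aicc_score(lnL: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aic_score(lnL: float, k: int) -> float:
    return -2.0 * lnL + 2.0 * k


def empirical_frequencies(aln: LocusAlignment,
                          pseudocount: float = 0.1) -> Tuple[float, ...]:
    arr = np.vstack([encode(s) for s in aln.sequences.values()])
    counts = np.array([(arr == s).sum() for s in range(4)], dtype=float)
    counts += pseudocount
    return tuple(counts / counts.sum())


def candidate_models(aln: LocusAlignment,
                     names: Sequence[str] = MODEL_NAMES
                     ) -> List[SubstitutionModel]:
    freqs = empirical_frequencies(aln)
    out = []
    for name in names:
        base = name.partition("+")[0]
        f = freqs if base in ("F81", "HKY85", "GTR") else (0.25,) * 4
        out.append(SubstitutionModel(name=name, freqs=f, kappa=2.0))
    return out


def _optimize_params(tl: TreeLikelihood,
                     model: SubstitutionModel) -> SubstitutionModel:
    base = model.base_name
    if base in ("K80", "HKY85"):
        def neg(logk: float) -> float:
            return -tl.log_likelihood(replace(model, kappa=float(np.exp(logk))))
        res = minimize_scalar(neg, bounds=(np.log(0.05), np.log(50.0)),
                              method="bounded", options={"xatol": 1e-3})
        model = replace(model, kappa=float(np.exp(res.x)))
    elif base == "GTR":
        def negv(logr: np.ndarray) -> float:
            rates = tuple(np.exp(logr)) + (1.0,)
            return -tl.log_likelihood(replace(model, rates=rates))
        x0 = np.zeros(5)
        res = minimize(negv, x0, method="L-BFGS-B",
                       bounds=[(-4, 4)] * 5, options={"maxiter": 40})
        model = replace(model, rates=tuple(np.exp(res.x)) + (1.0,))
    if model.gamma:
        def nega(loga: float) -> float:
            return -tl.log_likelihood(replace(model, alpha=float(np.exp(loga))))
        res = minimize_scalar(nega, bounds=(np.log(0.05), np.log(20.0)),
                              method="bounded", options={"xatol": 1e-3})
        model = replace(model, alpha=float(np.exp(res.x)))
    return model


def fit_model(aln: LocusAlignment, topology: Clade,
              model: SubstitutionModel) -> ModelFit:
    """Fit one model on a fixed topology: branch lengths by coordinate-wise
    line search, substitution parameters by ML, AICc with k including
    branch lengths (AIC fallback when n_sites <= k + 1, with a notice)."""
    tl = TreeLikelihood(aln, topology)
    tl.optimize_branch_lengths(model, sweeps=1)
    model = _optimize_params(tl, model)
    lnL = tl.optimize_branch_lengths(model, sweeps=2)
    k = model.k_free + tl.n_edges
    n = aln.length
    if n > k + 1:
        return ModelFit(aln.locus_id, model, lnL, aicc_score(lnL, k, n), n, k)
    log.info("%s: n_sites=%d <= k+1=%d; falling back to AIC",
             aln.locus_id, n, k + 1)
    return ModelFit(aln.locus_id, model, lnL, aic_score(lnL, k), n, k,
                    used_aic_fallback=True)


def _nj_topology(aln: LocusAlignment, max_distance: float = 5.0) -> Clade:
    dm = distance_matrix(aln, model="JC69", max_distance=max_distance)
    while dm.mask.any():
        worst = int(dm.mask.sum(axis=1).argmax())
        dm = dm.drop([dm.taxa[worst]])
    if len(dm.taxa) < 4:
        raise TooFewTaxaError(
            f"{aln.locus_id}: fewer than 4 taxa with shared data")
    return nj_clade(dm.matrix, dm.taxa)


def fit_all_models(aln: LocusAlignment,
                   names: Sequence[str] = MODEL_NAMES,
                   max_distance: float = 5.0) -> List[ModelFit]:
    if len(aln.present_taxa()) < 4:
        raise TooFewTaxaError(f"{aln.locus_id}: fewer than 4 taxa present")
    topo = _nj_topology(aln, max_distance)
    return [fit_model(aln, topo, m) for m in candidate_models(aln, names)]


def select_model_aicc(aln: LocusAlignment,
                      names: Sequence[str] = MODEL_NAMES,
                      max_distance: float = 5.0) -> ModelFit:
    """Best-fitting model by minimum AICc over the candidate set (ties keep
    the simpler model, i.e. the earlier entry in ``names``)."""
    fits = fit_all_models(aln, names, max_distance)
    best = fits[0]
    for f in fits[1:]:
        if f.aicc < best.aicc - 1e-9:
            best = f
    return best


def group_into_partitions(fits: Sequence[ModelFit]) -> Dict[str, List[str]]:
    """Group loci by selected model name; one partition per distinct model."""
    parts: Dict[str, List[str]] = {}
    for f in fits:
        parts.setdefault(f.model.name, []).append(f.locus_id)
    return parts
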