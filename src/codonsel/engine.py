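"""Likelihood core for codon substitution models.

The substitution process follows the classic codon-model construction:
instantaneous change between sense codons i and j is allowed only when
they differ at a single nucleotide position, with rate

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

up to a global scale chosen so the expected number of substitutions per
codon site per unit branch length is one.  kappa is the
transition/transversion rate ratio; omega = dN/dS measures selective
pressure on amino-acid changes.

Site-to-site variation in omega is expressed as a mixture of site
classes; branch-to-branch variation as a per-branch omega assignment.
The model families supported are:

* branch models M0 / MP / MA / MPA (one class, branch-label omegas,
  separate outgroup ratio);
* site models M8A (beta-distributed omega in 10 equal-weight categories
  plus a neutral class fixed at omega = 1) and M8 (the extra class free,
  omega_ad >= 1: positive selection), plus the discrete M3(k);
* the clade model MD(k): M3(k) in which one class's omega takes a
  different value in each of two designated clades.

Likelihoods are computed by Felsenstein pruning on the 61-state sense
codon alphabet with per-node scaling, after site-pattern compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import betainc, logsumexp
from scipy.stats import beta as beta_dist

from .genetics import MISSING, STANDARD_CODE, GeneticCode, is_transition
from .phylo import BranchPartition, LabeledPhylogeny
from .seqdata import CodonAlignment, CodonFrequencies

__all__ = [
    "RateMatrix",
    "SiteClassDistribution",
    "CodonModelSpec",
    "build_generator",
    "discretize_beta",
    "transition_probabilities",
    "log_likelihood",
    "class_structure",
    "BRANCH_FAMILIES",
    "SITE_FAMILIES",
]

BRANCH_FAMILIES = ("M0", "MP", "MA", "MPA")
SITE_FAMILIES = ("M3", "M8A", "M8", "MD")


def _pair_masks(code: GeneticCode) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = code.n_states
    single = np.zeros((n, n), dtype=bool)
    transit = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = code.single_difference(i, j)
            if d is None:
                continue
            single[i, j] = True
            _, a, b = d
            transit[i, j] = is_transition(a, b)
            nonsyn[i, j] = not code.is_synonymous(i, j)
    return single, transit, nonsyn

_SINGLE, _TRANSITION, _NONSYN = _pair_masks(STANDARD_CODE)


@dataclass
class RateMatrix:
    """Scaled reversible codon generator with its spectral factorisation.

    P(t) = exp(Qt) is obtained from the symmetrised form
    D Q D^{-1} (D = diag(sqrt(pi))), which has a real spectrum under
    detailed balance.
    """

    Q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float
    _spectral: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    def _decompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._spectral is None:
            d = np.sqrt(self.pi)
            sym = (self.Q * d[:, None]) / d[None, :]
            sym = 0.5 * (sym + sym.T)  # enforce exact symmetry
            lam, v = scipy.linalg.eigh(sym, check_finite=False)
            left = v / d[:, None]       # D^{-1} V
            right = v.T * d[None, :]    # V' D
            self._spectral = (lam, left, right)
        return self._spectral

    def probabilities(self, t: float) -> np.ndarray:
        """Transition matrix P(t) = exp(Qt)."""
        return self.probabilities_many(np.array([t]))[0]

    def probabilities_many(self, ts: np.ndarray) -> np.ndarray:
        """(len(ts), 61, 61) stack of transition matrices."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        lam, left, right = self._decompose()
        elt = np.exp(np.outer(ts, lam))            # (B, 61)
        out = (left[None, :, :] * elt[:, None, :]) @ right
        np.clip(out, 0.0, None, out=out)
        return out


def build_generator(
    kappa: float, omega: float, freqs: CodonFrequencies | np.ndarray
) -> RateMatrix:
    """Construct the scaled codon generator Q(kappa, omega, pi)."""
    pi = freqs.pi if isinstance(freqs, CodonFrequencies) else np.asarray(freqs, float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if np.any(pi <= 0):
        raise ValueError("zero equilibrium frequencies break reversibility")
    rate = np.where(_TRANSITION, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    Q = np.where(_SINGLE, rate * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale > 0:
        Q = Q / scale
    return RateMatrix(Q=Q, pi=pi, kappa=kappa, omega=omega)


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries in [0, 1]."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    return Q.probabilities(t)


# ---------------------------------------------------------------------------
# site-class distributions


@dataclass
class SiteClassDistribution:
    """Mixture of omega classes: (omega_c, weight_c) pairs."""

    omegas: np.ndarray
    weights: np.ndarray
    family: str = "discrete"

    def __post_init__(self) -> None:
        self.omegas = np.atleast_1d(np.asarray(self.omegas, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if self.omegas.shape != self.weights.shape:
            raise ValueError("omegas and weights must align")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def ncat(self) -> int:
        return len(self.omegas)


def discretize_beta(p: float, q: float, ncat: int = 10) -> SiteClassDistribution:
    """Discretize Beta(p, q) into ``ncat`` equal-probability categories.

    The omega of each category is the conditional mean of the beta over
    its quantile interval, computed from the regularized incomplete beta
    function: E[X | a < X < b] = (p/(p+q)) * (I(b; p+1, q) - I(a; p+1, q)) * ncat.
    """
    if not (np.isfinite(p) and np.isfinite(q) and p > 0 and q > 0):
        raise ValueError("beta shapes must be positive and finite")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    upper = betainc(p + 1.0, q, edges)
    means = (p / (p + q)) * np.diff(upper) * ncat
    # guard against degenerate categories in extreme shapes, keeping the
    # category values strictly increasing
    means = np.clip(means, 1e-9, 1.0 - 1e-9)
    for i in range(1, ncat):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] * (1.0 + 1e-12) + 1e-15
    weights = np.full(ncat, 1.0 / ncat)
    return SiteClassDistribution(omegas=means, weights=weights, family="beta")


def beta_plus_class(
    p: float, q: float, p_ad: float, omega_ad: float, ncat: int = 10
) -> SiteClassDistribution:
    """Beta-distributed purifying classes plus one additional class
    (neutral omega_ad = 1 for M8A; free omega_ad >= 1 for M8) with
    weight p_ad."""
    if not 0.0 <= p_ad <= 1.0:
        raise ValueError("p_ad must lie in [0, 1]")
    base = discretize_beta(p, q, ncat)
    omegas = np.append(base.omegas, omega_ad)
    weights = np.append(base.weights * (1.0 - p_ad), p_ad)
    fam = "beta10+1" if omega_ad == 1.0 else "beta10+free"
    return SiteClassDistribution(omegas=omegas, weights=weights, family=fam)


# ---------------------------------------------------------------------------
# model specification


@dataclass
class CodonModelSpec:
    """A model family plus the structural information needed to map a
    parameter dictionary onto per-class, per-branch omegas.

    ``partition`` carries the branch labeling (required for branch
    families and MD); ``k`` the class count for M3/MD; ``ncat_beta`` the
    number of beta categories for M8A/M8.
    """

    family: str
    k: int | None = None
    freq_scheme: str = "F3x4"
    ncat_beta: int = 10
    partition: BranchPartition | None = None

    def __post_init__(self) -> None:
        if self.family not in BRANCH_FAMILIES + SITE_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("M3", "MD") and (self.k is None or self.k < 2):
            raise ValueError(f"{self.family} requires k >= 2")
        if self.family in BRANCH_FAMILIES + ("MD",) and self.partition is None:
            raise ValueError(f"{self.family} requires a branch partition")

    @property
    def is_site_model(self) -> bool:
        return self.family in SITE_FAMILIES

    @property
    def positive_class(self) -> int | None:
        """Index of the class interpreted as the positive-selection /
        clade-divergent class, if any."""
        if self.family == "M8":
            return self.ncat_beta
        if self.family == "MD":
            return self.k - 1
        return None


def class_structure(
    model: CodonModelSpec,
    params: dict,
    tree: LabeledPhylogeny,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a model + parameter dict to mixture weights (C,) and a
    per-class, per-edge omega array (C, n_nodes) indexed by edge id."""
    n = tree.n_nodes
    fam = model.family
    if fam in BRANCH_FAMILIES:
        om = params["omega"]  # dict label -> value
        row = np.zeros(n)
        for e, lab in model.partition.labels.items():
            row[e] = om[lab]
        return np.array([1.0]), row[None, :]

    if fam in ("M8A", "M8"):
        omega_ad = 1.0 if fam == "M8A" else params["omega_ad"]
        dist = beta_plus_class(
            params["p"], params["q"], params["p_ad"], omega_ad, model.ncat_beta
        )
        return dist.weights, np.repeat(dist.omegas[:, None], n, axis=1)

    if fam == "M3":
        dist = SiteClassDistribution(params["omegas"], params["weights"])
        return dist.weights, np.repeat(dist.omegas[:, None], n, axis=1)

    if fam == "MD":
        # k-1 shared classes; the last class takes omega_a / omega_b on
        # the two clade branch sets
        shared = np.asarray(params["omegas"], float)
        if len(shared) != model.k - 1:
            raise ValueError(f"MD({model.k}) takes {model.k - 1} shared omegas")
        omegas = np.append(shared, 0.0)  # placeholder, overwritten below
        weights = np.asarray(params["weights"], float)
        grid = np.repeat(omegas[:, None], n, axis=1)
        div = model.k - 1
        for e, lab in model.partition.labels.items():
            grid[div, e] = params["omega_a"] if lab == "cladeA" else params["omega_b"]
        return weights, grid

    raise ValueError(fam)


# ---------------------------------------------------------------------------
# pruning likelihood


def compress_patterns(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns (columns), their counts, and the map from
    alignment sites back to pattern index."""
    patterns, inverse, counts = np.unique(
        codons.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts, inverse


def _all_class_loglik(
    patterns: np.ndarray,
    tip_of_row: np.ndarray,
    tree: LabeledPhylogeny,
    pi: np.ndarray,
    pstack: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of each pattern under every site class at once.

    ``pstack`` is (C, n_nodes, 61, 61): P(t_e) for edge e under class c
    (root slot unused).  Pruning is batched over the class axis.
    MISSING tip states contribute all-ones partials.  Returns (C, S).
    """
    C = pstack.shape[0]
    S = patterns.shape[1]
    n_states = pi.shape[0]
    row_of_tip = {int(t): r for r, t in enumerate(tip_of_row)}
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros((C, S))
    for v in tree.postorder:
        if not tree.children[v]:
            continue
        acc = None
        for c in tree.children[v]:
            P = pstack[:, c]  # (C, 61, 61)
            if not tree.children[c]:  # tip child: direct column lookup
                states = patterns[row_of_tip[c]]
                obs = states >= 0
                if obs.all():
                    msg = P[:, :, states].transpose(0, 2, 1)
                else:
                    msg = np.ones((C, S, n_states))
                    msg[:, obs, :] = P[:, :, states[obs]].transpose(0, 2, 1)
            else:
                msg = np.matmul(partials.pop(c), P.transpose(0, 2, 1))
            acc = msg.copy() if acc is None else acc.__imul__(msg)
        mx = acc.max(axis=2)
        mx = np.where(mx > 0, mx, 1.0)
        acc /= mx[:, :, None]
        logscale += np.log(mx)
        partials[v] = acc
    site = partials[tree.root] @ pi  # (C, S)
    return np.log(np.maximum(site, 1e-300)) + logscale


def tree_log_likelihood(
    codons: np.ndarray,
    taxa: list[str],
    tree: LabeledPhylogeny,
    pi: np.ndarray,
    kappa: float,
    weights: np.ndarray,
    omega_edges: np.ndarray,
    edge_lengths: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mixture log-likelihood over site classes by pruning.

    Returns the total log-likelihood and the per-site per-class
    log-likelihood table (n_sites, n_classes), i.e. log L_c(site) before
    mixing — the input to empirical-Bayes site posteriors.
    """
    missing = [t for t in taxa if t not in tree.tip_ids]
    if missing:
        raise ValueError(f"alignment taxa absent from tree: {missing}")
    lengths = tree.edge_length if edge_lengths is None else np.asarray(edge_lengths)
    tip_of_row = np.array([tree.tip_ids[t] for t in taxa])
    patterns, counts, inverse = compress_patterns(codons)
    edges = tree.edges

    # spectral decompositions shared across classes/branches with equal omega
    cache: dict[float, RateMatrix] = {}

    def rm(omega: float) -> RateMatrix:
        key = float(omega)
        if key not in cache:
            cache[key] = build_generator(kappa, key, pi)
        return cache[key]

    # group (class, edge) cells by omega so each generator exponentiates
    # all of its branch lengths in one vectorised call
    C = len(weights)
    n_states = pi.shape[0]
    pstack = np.empty((C, tree.n_nodes, n_states, n_states))
    by_omega: dict[float, list[tuple[int, int]]] = {}
    for c in range(C):
        for e in edges:
            by_omega.setdefault(float(omega_edges[c, e]), []).append((c, e))
    for om, cells in by_omega.items():
        ts = lengths[[e for _, e in cells]]
        mats = rm(om).probabilities_many(ts)
        for (c, e), P in zip(cells, mats):
            pstack[c, e] = P
    per_class = _all_class_loglik(patterns, tip_of_row, tree, pi, pstack)

    logw = np.log(np.maximum(weights, 1e-300))
    pattern_loglik = logsumexp(per_class + logw[:, None], axis=0)
    total = float(np.dot(counts, pattern_loglik))
    site_table = per_class.T[inverse]  # (n_sites, C)
    return total, site_table


def log_likelihood(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    model: CodonModelSpec,
    params: dict,
    pi: np.ndarray | CodonFrequencies,
    edge_lengths: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Model-level wrapper: expand the parameter dictionary through
    :func:`class_structure` and evaluate the pruning likelihood."""
    pi_vec = pi.pi if isinstance(pi, CodonFrequencies) else np.asarray(pi, float)
    weights, omega_edges = class_structure(model, params, tree)
    return tree_log_likelihood(
        aln.codons, aln.taxa, tree, pi_vec, params["kappa"],
        weights, omega_edges, edge_lengths,
    )
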