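"""Exploratory factor analysis of deregulated terms and GO-tree summarization.

The factor machinery follows the classical psychometrics pipeline: Horn's
parallel analysis to pick the number of factors (observed correlation-matrix
eigenvalues against a quantile of eigenvalues from same-shape standard-normal
data), principal-axis factoring with iterated communalities, and promax
(oblique) rotation via a varimax pre-rotation and a powered-target Procrustes
transform.  Salient terms (|loading| above a threshold) become each factor's
elements.

The merged factor elements are then summarized on the GO DAG: the
ancestor-closure subgraph induced by the terms is built, its connected
components are the clusters, and each cluster is labeled by its minimal
common ancestors — the lowest terms in the closure that are ancestors-or-self
of every member.  This formalizes "offspring terms cluster under common
ancestral terms" deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import GoDag

logger = logging.getLogger("funcgsr")

PA_RESAMPLES = 100
PA_QUANTILE = 0.95
EFA_TOL = 1e-4
EFA_MAX_ITER = 100
PROMAX_POWER = 4
LOADING_THRESHOLD = 0.4


@dataclass
class FactorSolution:
    term_names: list[str]
    n_factors: int
    loadings: np.ndarray  # terms x factors
    factor_correlations: np.ndarray | None = None
    communalities: np.ndarray | None = None
    rotation: str = "none"
    loading_threshold: float = LOADING_THRESHOLD
    assignment: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class ClusterSummary:
    """A connected cluster of GO terms labeled by its minimal common ancestors."""

    ancestor_ids: list[str]
    ancestor_names: list[str]
    member_terms: list[str]


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------


def parallel_analysis(
    X: np.ndarray,
    n_resamples: int = PA_RESAMPLES,
    quantile: float = PA_QUANTILE,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis on the correlation matrix of ``X``.

    Counts observed eigenvalues exceeding the per-rank ``quantile`` of
    eigenvalues from ``n_resamples`` standard-normal datasets of the same
    shape; counting stops at the first non-exceeding rank (retained factors
    must be consecutive from the top).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need >= 2 variables")
    if n <= 3:
        raise ValueError("need more than 3 samples")
    sd = X.std(axis=0)
    dead = [i for i in range(m) if sd[i] == 0]
    if dead:
        raise ValueError(f"constant columns at indices {dead[:10]}")
    obs_eigs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_resamples, m))
    for r in range(n_resamples):
        Z = rng.standard_normal((n, m))
        null_eigs[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.quantile(null_eigs, quantile, axis=0)
    count = 0
    for o, t in zip(obs_eigs, thresh):
        if o > t:
            count += 1
        else:
            break
    return count


# ---------------------------------------------------------------------------
# Principal-axis factoring
# ---------------------------------------------------------------------------


def fit_efa(X: np.ndarray, n_factors: int, term_names: list[str] | None = None) -> FactorSolution:
    """Principal-axis factoring of the correlation matrix of ``X``.

    Communalities are initialized at squared multiple correlations and
    iterated (eigendecomposition of the reduced correlation matrix, new
    communalities = loading row sums of squares) until the largest change is
    below 1e-4 or 100 iterations.  Heywood communalities are clipped to 1 with
    a warning.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if term_names is None:
        term_names = [f"V{i}" for i in range(m)]
    if not 1 <= n_factors < m:
        raise ValueError(f"n_factors must be in [1, {m - 1}]")
    R = np.corrcoef(X, rowvar=False)
    return _paf_from_corr(R, n_factors, term_names)


def _paf_from_corr(R: np.ndarray, n_factors: int, term_names: list[str]) -> FactorSolution:
    m = R.shape[0]
    # initial communalities: squared multiple correlations
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.abs(R - np.eye(m)).max(axis=1) ** 2
    h2 = np.clip(h2, 0.0, 1.0)
    loadings = None
    for it in range(EFA_MAX_ITER):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[order], 0.0, None)
        loadings = vecs[:, order] * np.sqrt(lam)
        new_h2 = (loadings**2).sum(axis=1)
        if (new_h2 > 1).any():
            warnings.warn("Heywood case: communality > 1 clipped", RuntimeWarning)
            new_h2 = np.clip(new_h2, 0.0, 1.0)
        delta = np.abs(new_h2 - h2).max()
        h2 = new_h2
        if delta < EFA_TOL:
            break
    else:
        logger.warning("principal-axis factoring stopped at %d iterations "
                       "(last communality change %.2e)", EFA_MAX_ITER, float(delta))
    # sign convention: each factor's largest-|loading| entry is positive
    for k in range(n_factors):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    return FactorSolution(
        term_names=list(term_names),
        n_factors=n_factors,
        loadings=loadings,
        communalities=h2,
        rotation="none",
    )


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------


def _varimax(L: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalization."""
    m, k = L.shape
    if k < 2:
        return np.eye(1)
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        grad = A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / m)
        U, s, Vt = np.linalg.svd(grad)
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return T


def promax_rotate(solution: FactorSolution, power: int = PROMAX_POWER) -> FactorSolution:
    """Promax oblique rotation (varimax pre-rotation, powered-target fit).

    With one factor the rotation is the identity.  Returns the pattern
    loadings and the factor correlation matrix; communalities (diagonal of
    ``P Phi P'``) are preserved by construction.
    """
    L = solution.loadings
    m, k = L.shape
    if k == 1:
        return FactorSolution(
            term_names=list(solution.term_names),
            n_factors=1,
            loadings=L.copy(),
            factor_correlations=np.eye(1),
            communalities=solution.communalities,
            rotation="promax",
            loading_threshold=solution.loading_threshold,
        )
    T = _varimax(L)
    V = L @ T
    # powered target: sign-preserving elementwise power
    P_target = np.abs(V) ** (power - 1) * V
    # per-factor least squares V @ coef ~= target
    coef, *_ = np.linalg.lstsq(V, P_target, rcond=None)
    try:
        d = np.sqrt(np.diag(np.linalg.inv(coef.T @ coef)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular promax transform") from exc
    coef = coef * d
    pattern = V @ coef
    phi = np.linalg.inv(coef.T @ coef)
    for k_i in range(k):
        j = np.argmax(np.abs(pattern[:, k_i]))
        if pattern[j, k_i] < 0:
            pattern[:, k_i] *= -1
            phi[k_i, :] *= -1
            phi[:, k_i] *= -1
    return FactorSolution(
        term_names=list(solution.term_names),
        n_factors=k,
        loadings=pattern,
        factor_correlations=phi,
        communalities=solution.communalities,
        rotation="promax",
        loading_threshold=solution.loading_threshold,
    )


def assign_elements(solution: FactorSolution, threshold: float = LOADING_THRESHOLD) -> dict[int, list[str]]:
    """Assign each term to every factor where |loading| >= threshold.

    Multi-assignment is allowed; terms salient on no factor are collected
    under key ``-1``.  The assignment is also stored on the solution.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    assignment: dict[int, list[str]] = {k: [] for k in range(solution.n_factors)}
    unassigned = []
    for i, term in enumerate(solution.term_names):
        hit = False
        for k in range(solution.n_factors):
            if abs(solution.loadings[i, k]) >= threshold:
                assignment[k].append(term)
                hit = True
        if not hit:
            unassigned.append(term)
    if not any(assignment.values()):
        logger.warning("no term reaches |loading| >= %.2f on any factor", threshold)
    assignment[-1] = unassigned
    solution.assignment = assignment
    solution.loading_threshold = threshold
    return assignment


def merged_elements(assignment: dict[int, list[str]]) -> list[str]:
    """Union of all factors' salient terms (the default GO-tree input)."""
    out: set[str] = set()
    for k, terms in assignment.items():
        if k >= 0:
            out.update(terms)
    return sorted(out)


# ---------------------------------------------------------------------------
# GO-tree summarization
# ---------------------------------------------------------------------------


def map_to_dag(terms: list[str], dag: GoDag) -> list[ClusterSummary]:
    """Cluster terms by connectivity of their ancestor-closure subgraph.

    Unresolvable terms are reported and skipped.  Each connected component of
    the closure (terms plus all their ancestors) is one cluster; its label is
    the set of minimal common ancestors: the lowest closure terms that are
    ancestors-or-self of every member term in the component.
    """
    if not terms:
        raise ValueError("empty term list")
    g = dag.to_networkx()  # child -> parent
    resolved = [t for t in terms if t in g]
    skipped = [t for t in terms if t not in g]
    if skipped:
        logger.warning("%d terms not in DAG, skipped: %s", len(skipped), skipped[:5])
    if not resolved:
        raise ValueError("no input terms resolve to DAG terms")

    anc: dict[str, set[str]] = {t: {t} | nx.descendants(g, t) for t in resolved}
    closure = set().union(*anc.values())
    sub = g.subgraph(closure).to_undirected()

    clusters: list[ClusterSummary] = []
    for comp in nx.connected_components(sub):
        members = sorted(t for t in resolved if t in comp)
        if not members:
            continue
        common = set.intersection(*(anc[t] for t in members))
        # minimal = no other common ancestor lies strictly below it
        minimal = sorted(
            a for a in common
            if not any(a in nx.descendants(g, b) for b in common if b != a)
        )
        clusters.append(
            ClusterSummary(
                ancestor_ids=minimal,
                ancestor_names=[dag.terms.get(a, a) for a in minimal],
                member_terms=members,
            )
        )
    clusters.sort(key=lambda c: (-len(c.member_terms), c.ancestor_ids))
    return clusters
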