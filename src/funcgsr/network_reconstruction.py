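"""Function-interaction network from mutual information + ARACNE pruning.

Pairwise dependence between gene sets' GSR vectors is estimated with the
first Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbor estimator

    MI = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >

with max-norm neighborhoods, clipped below at zero.  GSR vectors are
discrete-ish (pair-count fractions), so a tiny seeded jitter breaks ties
before estimation.  Indirect edges are removed by ARACNE's data-processing
inequality: in every triangle, the weakest edge is dropped when it falls
below the smaller of the other two scaled by ``1 - tolerance``
(the multiplicative DPI variant); all removals are decided against the
original matrix and applied simultaneously.  An edge floor defaults to a
permutation-null quantile of the MI distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .gsr_core import FunctionomeMatrix, compute_functionome
from .io_formats import ExpressionDataset, GeneSetCollection

logger = logging.getLogger("funcgsr")

KSG_K = 3
DPI_TOLERANCE = 0.05
JITTER_SD = 1e-10
NULL_PERMUTATIONS = 100
NULL_QUANTILE = 0.95


@dataclass
class MiNetwork:
    """Undirected MI network over gene sets (one record per unordered pair)."""

    nodes: dict[str, dict]  # name -> attributes (deregulated, q, ...)
    edges: list[tuple[str, str, float]]
    dpi_tolerance: float = DPI_TOLERANCE
    k_neighbors: int = KSG_K
    mi_floor: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for u, v, mi in self.edges:
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if mi < 0:
                raise ValueError(f"negative MI on ({u}, {v})")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u}, {v})")
            seen.add(key)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, attrs in self.nodes.items():
            g.add_node(name, **attrs)
        for u, v, mi in self.edges:
            g.add_edge(u, v, weight=float(mi))
        return g


# ---------------------------------------------------------------------------
# KSG mutual information
# ---------------------------------------------------------------------------


def knn_mutual_information(
    x, y, k: int = KSG_K, jitter_sd: float | None = None, seed: int = 0
) -> float:
    """KSG-1 mutual information estimate in nats, clipped below at 0.

    ``jitter_sd`` adds seeded Gaussian jitter to both vectors before
    estimation; without it, constant or exactly tied inputs are an error
    (k-NN distances degenerate at zero).
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 2 * k + 2:
        raise ValueError(f"need >= {2 * k + 2} observations for k={k}")
    if jitter_sd:
        rng = np.random.default_rng(seed)
        x += rng.normal(0.0, jitter_sd, size=n)
        y += rng.normal(0.0, jitter_sd, size=n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector (enable jitter for tied data)")
    return _ksg(x, y, k)


def _ksg(x: np.ndarray, y: np.ndarray, k: int) -> float:
    n = len(x)
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # distance to the k-th neighbor in max-norm (exclude self)
    dists, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dists[:, -1]
    if np.any(eps == 0):
        raise ValueError(
            "tied samples give a zero k-NN distance; enable jitter for "
            "discrete or duplicated data"
        )
    # strictly-within-eps marginal counts
    nx_ = _marginal_counts(x, eps)
    ny_ = _marginal_counts(y, eps)
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    return float(max(mi, 0.0))


def _marginal_counts(v: np.ndarray, eps: np.ndarray) -> np.ndarray:
    order = np.argsort(v)
    sv = v[order]
    lo = np.searchsorted(sv, v - eps, side="right")
    hi = np.searchsorted(sv, v + eps, side="left")
    return np.maximum(hi - lo - 1, 0)  # exclude the point itself


def mi_matrix(
    X: np.ndarray, k: int = KSG_K, jitter_sd: float = JITTER_SD, seed: int = 0
) -> np.ndarray:
    """Symmetric MI matrix over the columns of ``X`` (zero diagonal).

    Jitter is applied once per column (seeded), so the matrix is exactly
    symmetric and reproducible.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    Xj = X + rng.normal(0.0, jitter_sd, size=X.shape)
    m = X.shape[1]
    out = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        out[i, j] = out[j, i] = _ksg(Xj[:, i], Xj[:, j], k)
    return out


def permutation_mi_floor(
    X: np.ndarray,
    k: int = KSG_K,
    n_permutations: int = NULL_PERMUTATIONS,
    quantile: float = NULL_QUANTILE,
    jitter_sd: float = JITTER_SD,
    seed: int = 0,
) -> float:
    """MI floor = the ``quantile`` of a permutation null: MI between randomly
    chosen columns after independently shuffling one of them."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    m = X.shape[1]
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        i, j = rng.choice(m, size=2, replace=False)
        x = X[:, i] + rng.normal(0.0, jitter_sd, size=X.shape[0])
        y = rng.permutation(X[:, j]) + rng.normal(0.0, jitter_sd, size=X.shape[0])
        null[t] = _ksg(x, y, k)
    return float(np.quantile(null, quantile))


# ---------------------------------------------------------------------------
# ARACNE pruning
# ---------------------------------------------------------------------------


def aracne_prune(
    mi: np.ndarray,
    names: list[str] | None = None,
    dpi_tolerance: float = DPI_TOLERANCE,
    mi_floor: float = 0.0,
    node_attrs: dict[str, dict] | None = None,
    k_neighbors: int = KSG_K,
) -> MiNetwork:
    """Apply the edge floor then the data-processing inequality.

    Edge (i, j) is removed when some third node k has
    ``mi[i, j] < min(mi[i, k], mi[j, k]) * (1 - tolerance)`` with both other
    edges above the floor.  All decisions use the original matrix.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.ndim != 2 or mi.shape[0] != mi.shape[1]:
        raise ValueError("MI matrix must be square")
    if not np.allclose(mi, mi.T):
        raise ValueError("MI matrix must be symmetric")
    m = mi.shape[0]
    if names is None:
        names = [f"N{i}" for i in range(m)]
    present = mi >= mi_floor
    np.fill_diagonal(present, False)

    keep: list[tuple[str, str, float]] = []
    for i, j in itertools.combinations(range(m), 2):
        if not present[i, j]:
            continue
        removed = False
        for t in range(m):
            if t == i or t == j or not (present[i, t] and present[j, t]):
                continue
            if mi[i, j] < min(mi[i, t], mi[j, t]) * (1.0 - dpi_tolerance):
                removed = True
                break
        if not removed:
            keep.append((names[i], names[j], float(mi[i, j])))

    nodes = {n: dict((node_attrs or {}).get(n, {})) for n in names}
    return MiNetwork(
        nodes=nodes,
        edges=keep,
        dpi_tolerance=dpi_tolerance,
        k_neighbors=k_neighbors,
        mi_floor=mi_floor,
    )


# ---------------------------------------------------------------------------
# Merged-cancer network
# ---------------------------------------------------------------------------


def merge_and_network(
    cohorts: dict[str, tuple[ExpressionDataset, ExpressionDataset]],
    collection: GeneSetCollection,
    dereg_q: dict[str, float] | None = None,
    diseases: tuple[str, str] = ("CCC", "EC"),
    k: int = KSG_K,
    dpi_tolerance: float = DPI_TOLERANCE,
    mi_floor: float | None = None,
    significance_level: float = 0.01,
    include_controls: bool = False,
    seed: int = 0,
    min_common_genes: int = 2,
) -> tuple[MiNetwork, FunctionomeMatrix]:
    """Merged-cancer MI network: pool both cancers' cases, re-learn templates
    from the pooled tissue-matched controls, recompute GSR, estimate pairwise
    MI across the merged case samples, floor + DPI-prune.

    Node attribute ``deregulated`` flags terms with BH-q below the
    significance level in the merged case-vs-control comparison (or pass
    precomputed q values via ``dereg_q``).
    """
    from .deregulation_stats import build_table
    from .gsr_core import integrate_common_genes

    missing = [d for d in diseases if d not in cohorts]
    if missing:
        raise ValueError(f"cohorts missing diseases: {missing}")
    parts = []
    for d in diseases:
        case, ctrl = cohorts[d]
        parts.extend([case, ctrl])
    merged = integrate_common_genes(parts, min_common_genes=min_common_genes)
    # one pooled disease label so a single table covers the merged cohort
    for s, lab in merged.sample_labels.items():
        lab["disease"] = "+".join(diseases)
    fm = compute_functionome(merged, collection)

    if dereg_q is None:
        table = build_table(fm, "+".join(diseases))
        dereg_q = table["q"].to_dict()

    mask = fm.rows_for(group="case")
    if include_controls:
        mask = np.ones(len(fm.sample_ids), dtype=bool)
    X = fm.gsr[mask, :]
    M = mi_matrix(X, k=k, seed=seed)
    if mi_floor is None:
        mi_floor = permutation_mi_floor(X, k=k, seed=seed + 1)
        logger.info("permutation-null MI floor: %.4f nats", mi_floor)
    node_attrs = {
        name: {
            "q": float(dereg_q.get(name, np.nan)),
            "deregulated": bool(dereg_q.get(name, 1.0) < significance_level),
        }
        for name in fm.set_names
    }
    net = aracne_prune(
        M,
        names=fm.set_names,
        dpi_tolerance=dpi_tolerance,
        mi_floor=mi_floor,
        node_attrs=node_attrs,
        k_neighbors=k,
    )
    net.meta["n_merged_cases"] = int(fm.rows_for(group="case").sum())
    return net, fm


def largest_subnetwork(network: MiNetwork) -> MiNetwork:
    """Restrict to the largest connected component (isolated nodes are
    singleton components); ties go to the component whose smallest member
    name sorts first."""
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    comp = comps[0]
    return MiNetwork(
        nodes={n: dict(network.nodes[n]) for n in sorted(comp)},
        edges=[(u, v, w) for u, v, w in network.edges if u in comp and v in comp],
        dpi_tolerance=network.dpi_tolerance,
        k_neighbors=network.k_neighbors,
        mi_floor=network.mi_floor,
        meta=dict(network.meta),
    )
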