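"""The three clustering engines behind the consensus signature.

* ``mcl`` — Markov clustering of a thresholded Pearson-correlation graph
  (edges at r >= 0.85 for RNA, 0.8 for protein): iterated expansion (matrix
  squaring of the column-stochastic walk matrix with self-loops) and
  inflation (elementwise powering with column renormalization) until the
  matrix decomposes into attractor systems.
* ``wcna`` — weighted correlation network analysis: soft-thresholded
  unsigned adjacency |r|^beta, topological-overlap dissimilarity,
  average-linkage hierarchical clustering with a static height cut, module
  eigengenes (first principal component of the module's standardized
  expression) and iterative eigengene merging below a dissimilarity
  threshold.
* ``som_train`` — a 5x5 online self-organizing map over z-transformed gene
  profiles with linearly decaying learning rate and Gaussian neighborhood.

``select_effector_cluster`` scores each cluster's population profile and
picks the one high in both CX3CR1+ populations and low elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse
import scipy.spatial.distance

from .io_formats import ALL_POPULATIONS, CX3CR1_POSITIVE, PopulationLabel

logger = logging.getLogger("cx3sig.netclust")


# ---------------------------------------------------------------------------
# correlation graph
# ---------------------------------------------------------------------------

def correlation_graph(matrix: pd.DataFrame, min_r: float) -> nx.Graph:
    """Graph over genes with an edge wherever Pearson r >= ``min_r``.

    Zero-variance genes cannot carry a correlation and are excluded with a
    warning. The threshold is stored as the graph attribute ``min_r``; edge
    weights are the correlations.
    """
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("correlation graph: %d zero-variance genes excluded",
                       int((~ok).sum()))
    genes = matrix.index[ok]
    g = nx.Graph(min_r=min_r)
    g.add_nodes_from(genes)
    if ok.sum() >= 2:
        r = np.corrcoef(vals[ok])
        iu, ju = np.triu_indices_from(r, k=1)
        hit = r[iu, ju] >= min_r
        g.add_weighted_edges_from(
            (genes[i], genes[j], float(r[i, j]))
            for i, j in zip(iu[hit], ju[hit])
        )
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Disjoint gene clusters plus the unassigned (singleton) pool."""

    clusters: list[frozenset[str]]
    unassigned: frozenset[str]
    converged: bool = True

    def all_nodes(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for c in self.clusters:
            out |= c
        return frozenset(out)


def _mcl_matrix(m: scipy.sparse.csr_matrix, inflation: float, max_iter: int,
                tol: float, prune: float = 1e-9):
    """Run the expansion/inflation loop on a column-stochastic sparse matrix."""
    converged = False
    for _ in range(max_iter):
        prev = m
        m = (m @ m).tocsc()
        m.data = np.power(m.data, inflation)
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        colsum = np.asarray(m.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        m = m.multiply(scipy.sparse.csr_matrix(1.0 / colsum)).tocsr()
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    return m.tocsr(), converged


def mcl(graph: nx.Graph, inflation: float = 2.2, max_iter: int = 200,
        tol: float = 1e-6) -> ClusterSet:
    """Classic Markov clustering of an undirected weighted graph.

    Self-loops of weight 1 are added, columns are normalized to a stochastic
    walk matrix, and expansion (squaring) alternates with inflation
    (elementwise power + renormalization) until the change drops below
    ``tol``. Clusters are the connected attractor systems of the limit
    matrix; singletons are reported as unassigned. Non-convergence at
    ``max_iter`` returns the current interpretation with ``converged=False``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("MCL requires a non-empty graph")
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for a, b, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        if a == b:
            continue
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
        data += [w, w]
    rows += list(range(n))
    cols += list(range(n))
    data += [1.0] * n  # self-loops
    m = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    colsum = np.asarray(m.sum(axis=0)).ravel()
    m = m.multiply(scipy.sparse.csr_matrix(1.0 / colsum)).tocsr()

    m, converged = _mcl_matrix(m, inflation, max_iter, tol)
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    # clusters = connected components of the limit matrix's support
    support = m + m.T
    ncomp, membership = scipy.sparse.csgraph.connected_components(
        support, directed=False
    )
    groups: dict[int, set[str]] = {}
    for node, comp in zip(nodes, membership):
        groups.setdefault(comp, set()).add(node)
    clusters = [frozenset(g) for g in groups.values() if len(g) > 1]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    unassigned = frozenset(
        x for g in groups.values() if len(g) == 1 for x in g
    )
    return ClusterSet(clusters=clusters, unassigned=unassigned,
                      converged=converged)


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMGrid:
    """Trained self-organizing map over gene expression profiles."""

    codebook: np.ndarray           # units x samples
    grid_shape: tuple[int, int]
    assignment: pd.Series          # gene -> unit index
    iterations: int
    eigen_profiles: pd.DataFrame   # unit x population summary
    qe_history: list[float] = field(default_factory=list)


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
    return np.column_stack([rows.ravel(), cols.ravel()]).astype(float)


def som_train(zmatrix: pd.DataFrame, labels: dict[str, PopulationLabel],
              n_units: int = 25, iterations: int = 20000,
              seed: int = 0, n_checkpoints: int = 0) -> SOMGrid:
    """Online SOM training of gene profiles on a square grid.

    ``n_units`` must be a perfect square (default 25 -> 5x5 rectangular
    grid). Learning rate decays linearly 0.05 -> 0.01 and the Gaussian
    neighborhood radius 2 -> 0.5 over ``iterations`` single-gene updates.
    After training each gene is assigned to its best-matching unit; each
    unit's profile summary is the first eigenvector of its member genes'
    population-mean profiles, sign-fixed to a positive mean. With
    ``n_checkpoints > 0`` the quantization error over the full data is
    recorded at that many evenly spaced points during training.
    """
    side = int(round(np.sqrt(n_units)))
    if side * side != n_units:
        raise ValueError("n_units must be a perfect square")
    x = zmatrix.to_numpy(dtype=float)
    n_genes, dim = x.shape
    if n_genes < n_units:
        logger.warning("fewer genes (%d) than SOM units (%d); some units "
                       "will be empty", n_genes, n_units)
    rng = np.random.default_rng(seed)
    codebook = x[rng.integers(0, n_genes, size=n_units)].astype(float).copy()
    coords = _grid_coords((side, side))

    checkpoints = set()
    if n_checkpoints > 0:
        checkpoints = set(
            np.linspace(iterations // n_checkpoints, iterations,
                        n_checkpoints, dtype=int)
        )
    qe_history: list[float] = []
    lr0, lr1 = 0.05, 0.01
    rad0, rad1 = 2.0, 0.5
    for t in range(iterations):
        frac = t / max(iterations - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        rad = rad0 + (rad1 - rad0) * frac
        v = x[rng.integers(0, n_genes)]
        bmu = int(np.argmin(((codebook - v) ** 2).sum(axis=1)))
        d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
        h = np.exp(-d2 / (2 * rad * rad))
        codebook += (lr * h)[:, None] * (v - codebook)
        if (t + 1) in checkpoints:
            qe_history.append(quantization_error(zmatrix, codebook))

    d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    assignment = pd.Series(np.argmin(d, axis=1), index=zmatrix.index,
                           name="unit")

    # per-unit summary of member genes' population-mean profiles
    lab = pd.Series({s: labels[s] for s in zmatrix.columns})
    pops = [p for p in ALL_POPULATIONS if p in set(lab)]
    gmeans = pd.DataFrame(
        {p.value: zmatrix[[s for s in zmatrix.columns if lab[s] == p]].mean(axis=1)
         for p in pops}
    )
    profiles = np.full((n_units, len(pops)), np.nan)
    for u in range(n_units):
        members = gmeans[assignment == u].to_numpy()
        if members.shape[0] == 0:
            continue
        if members.shape[0] == 1:
            vec = members[0]
        else:
            _, _, vt = np.linalg.svd(members - members.mean(axis=0),
                                     full_matrices=False)
            vec = vt[0]
            if members.mean(axis=0) @ vec < 0:
                vec = -vec
            vec = vec * np.linalg.norm(members.mean(axis=0))
        if vec.mean() < 0:
            vec = -vec
        profiles[u] = vec
    return SOMGrid(
        codebook=codebook,
        grid_shape=(side, side),
        assignment=assignment,
        iterations=iterations,
        eigen_profiles=pd.DataFrame(profiles, columns=[p.value for p in pops]),
        qe_history=qe_history,
    )


def quantization_error(zmatrix: pd.DataFrame, codebook: np.ndarray) -> float:
    """Mean Euclidean distance of each gene to its best-matching unit."""
    x = zmatrix.to_numpy(dtype=float)
    d = np.sqrt(((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# weighted correlation network analysis
# ---------------------------------------------------------------------------

@dataclass
class Module:
    genes: frozenset[str]
    eigengene: pd.Series  # per-sample, unit length, sign-fixed


@dataclass
class ModuleSet:
    modules: list[Module]
    unassigned: frozenset[str]
    power: float
    min_module: int
    mediss: float

    def gene_sets(self) -> list[frozenset[str]]:
        return [m.genes for m in self.modules]


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    zero diagonal in the adjacency and omega_ii = 1.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(z: pd.DataFrame) -> pd.Series:
    """First principal component of a module's standardized expression,
    unit length, sign-fixed so the mean member correlation is positive."""
    x = z.to_numpy(dtype=float)
    _, _, vt = np.linalg.svd(x - x.mean(axis=1, keepdims=True),
                             full_matrices=False)
    e = vt[0]
    cors = np.array([np.corrcoef(row, e)[0, 1] for row in x])
    if np.nanmean(cors) < 0:
        e = -e
    return pd.Series(e, index=z.columns)


def _zrows(matrix: pd.DataFrame) -> pd.DataFrame:
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    return matrix.sub(mu, axis=0).div(sd, axis=0)


def _static_cut(linkage: np.ndarray, min_module: int,
                max_heights: int = 512) -> np.ndarray:
    """Cut the dendrogram at the height maximizing the number of branches of
    size >= min_module; among ties, the lowest height wins."""
    heights = np.unique(linkage[:, 2])
    if len(heights) > max_heights:
        qs = np.linspace(0, 1, max_heights)
        heights = np.quantile(heights, qs)
        heights = np.unique(heights)
    best = None
    best_count = -1
    eps = 1e-12
    for h in heights:
        memb = scipy.cluster.hierarchy.fcluster(linkage, t=h + eps,
                                                criterion="distance")
        sizes = np.bincount(memb)
        count = int((sizes >= min_module).sum())
        if count > best_count:
            best_count = count
            best = memb
    return best


def wcna(matrix: pd.DataFrame, power: float, min_module: int = 30,
         mediss: float = 0.3) -> ModuleSet:
    """Weighted correlation network module detection with eigengene merging.

    Unsigned soft-thresholded adjacency ``|r|^power`` over genes (rows of
    ``matrix``), 1 - TOM dissimilarity, average-linkage clustering, static
    height cut (maximal number of branches >= ``min_module``), then modules
    whose eigengenes are closer than ``mediss`` (1 - correlation) are merged
    iteratively, recomputing eigengenes after each merge.
    """
    if len(matrix) < min_module:
        raise ValueError(
            f"need at least min_module={min_module} genes, got {len(matrix)}"
        )
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = list(matrix.index[sd == 0][:10])
        raise ValueError(f"zero-variance genes break the correlation matrix: "
                         f"{bad}")
    r = np.corrcoef(vals)
    if not np.isfinite(r).all():
        bad = list(matrix.index[~np.isfinite(r).all(axis=1)][:10])
        raise ValueError(f"degenerate correlations for genes: {bad}")
    adj = np.abs(r) ** power
    tom = topological_overlap(adj)
    diss = 1.0 - tom
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    condensed = scipy.spatial.distance.squareform(diss, checks=False)
    link = scipy.cluster.hierarchy.average(condensed)
    memb = _static_cut(link, min_module)

    z = _zrows(matrix)
    modules: list[Module] = []
    unassigned: set[str] = set()
    for cid in np.unique(memb):
        genes = matrix.index[memb == cid]
        if len(genes) >= min_module:
            modules.append(Module(frozenset(genes), _eigengene(z.loc[genes])))
        else:
            unassigned.update(genes)
    modules.sort(key=lambda m: (-len(m.genes), min(m.genes)))
    logger.info("wcna: %d candidate modules, %d unassigned genes",
                len(modules), len(unassigned))

    modules = _merge_modules(modules, z, mediss)
    return ModuleSet(modules=modules, unassigned=frozenset(unassigned),
                     power=power, min_module=min_module, mediss=mediss)


def _merge_modules(modules: list[Module], z: pd.DataFrame,
                   mediss: float) -> list[Module]:
    """Iteratively merge the closest eigengene pair while below ``mediss``."""
    modules = list(modules)
    while len(modules) > 1:
        k = len(modules)
        dis = np.full((k, k), np.inf)
        for i in range(k):
            for j in range(i + 1, k):
                c = np.corrcoef(modules[i].eigengene, modules[j].eigengene)[0, 1]
                dis[i, j] = 1.0 - c
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= mediss:
            break
        merged_genes = modules[i].genes | modules[j].genes
        merged = Module(merged_genes, _eigengene(z.loc[list(merged_genes)]))
        modules = [m for idx, m in enumerate(modules) if idx not in (i, j)]
        modules.append(merged)
        modules.sort(key=lambda m: (-len(m.genes), min(m.genes)))
    return modules


# ---------------------------------------------------------------------------
# effector-cluster selection
# ---------------------------------------------------------------------------

def select_effector_cluster(
    clusters: list[frozenset[str]], group_mean_z: pd.DataFrame
) -> tuple[frozenset[str], float]:
    """Pick the cluster high in both CX3CR1+ populations, low elsewhere.

    score(C) = min over CX3CR1+ groups of the cluster's mean z minus the max
    over the remaining groups; returns (argmax cluster, score). Ties go to
    the larger cluster, then to the lexicographically first member gene.
    """
    if not clusters:
        raise ValueError("no clusters to select from")
    pos_cols = [p.value for p in ALL_POPULATIONS if p in CX3CR1_POSITIVE]
    other_cols = [p.value for p in ALL_POPULATIONS
                  if p not in CX3CR1_POSITIVE and p.value in group_mean_z.columns]
    best = None
    for c in clusters:
        genes = [g for g in c if g in group_mean_z.index]
        if not genes:
            continue
        prof = group_mean_z.loc[genes].mean(axis=0)
        score = prof[pos_cols].min() - prof[other_cols].max()
        # larger score, then larger cluster, then lexicographically first gene
        if best is None or (score, len(c)) > (best[1], len(best[0])) or (
            (score, len(c)) == (best[1], len(best[0])) and min(c) < min(best[0])
        ):
            best = (c, float(score))
    if best is None:
        raise ValueError("no cluster overlaps the expression matrix")
    return best
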