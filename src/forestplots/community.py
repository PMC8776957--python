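"""Composition-based community analysis, implemented from definitions.

Hellinger transformation and distance, UPGMA agglomeration with
cophenetic-correlation model selection, silhouette and Mantel
cluster-number diagnostics, non-metric multidimensional scaling
(Kruskal stress-1), distance-based permutational MANOVA, and the
Dufrene-Legendre indicator-value (IndVal) statistic.

Sampling units here are plots; a subplot-level cover matrix is pooled
to plot level (summed covers) before any of these analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datagen import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Ordination",
    "PermanovaTable",
    "IndValResult",
    "hellinger_transform",
    "hellinger_distance",
    "bray_curtis_distance",
    "euclidean_distance",
    "upgma",
    "cophenetic_distances",
    "cophenetic_correlation",
    "select_clustering",
    "silhouette_widths",
    "mantel_cluster_statistic",
    "choose_k",
    "nmds",
    "permanova",
    "indval",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, labelled by unit."""

    units: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.units)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match unit count")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if (m < 0).any():
            raise ValueError("distances must be >= 0")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.units)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.units, columns=self.units)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration schedule: (left, right, height, size) per merge.

    Cluster ids follow the scipy linkage convention: leaves are
    0..n-1, the cluster created by merge ``m`` is ``n + m``.
    """

    leaves: tuple[str, ...]
    merges: np.ndarray  # (n-1, 4)

    @property
    def n(self) -> int:
        return len(self.leaves)

    def to_linkage(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0-based) for exactly k clusters."""
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.to_linkage(), t=k, criterion="maxclust") - 1

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            # ultrametric convention: node depth = half its merge height
            la = h / 2 - height[a] / 2
            lb = h / 2 - height[b] / 2
            node[n + m] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + m] = h
        return node[n + self.n - 2] + ";"


# --- distances -----------------------------------------------------------


def hellinger_transform(cover: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Square-root relative abundance per row; row sums of squares are 1."""
    df = cover.df if isinstance(cover, AbundanceMatrix) else cover
    x = df.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = df.index[totals <= 0].tolist()
        raise ValueError(f"all-zero abundance row(s): {bad}")
    return pd.DataFrame(
        np.sqrt(x / totals[:, None]), index=df.index, columns=df.columns
    )


def hellinger_distance(cover: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between Hellinger-transformed rows; max sqrt(2)."""
    t = hellinger_transform(cover)
    d = squareform(pdist(t.to_numpy(), metric="euclidean"))
    return DistanceMatrix(tuple(t.index), d)


def bray_curtis_distance(cover: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    df = cover.df if isinstance(cover, AbundanceMatrix) else cover
    d = squareform(pdist(df.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(tuple(df.index), d)


def euclidean_distance(cover: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    df = cover.df if isinstance(cover, AbundanceMatrix) else cover
    d = squareform(pdist(df.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(tuple(df.index), d)


DISTANCES: Mapping[str, Callable[[AbundanceMatrix], DistanceMatrix]] = {
    "hellinger": hellinger_distance,
    "braycurtis": bray_curtis_distance,
    "euclidean": euclidean_distance,
}


# --- hierarchical clustering ---------------------------------------------


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group average-linkage agglomeration.

    The distance between two clusters is the unweighted mean of all
    between-leaf distances, maintained by the size-weighted update
    d(A+B, X) = (|A| d(A,X) + |B| d(B,X)) / (|A| + |B|).  Ties break on
    the smallest cluster-id pair, so the schedule is deterministic.
    """
    n = dist.n
    if n < 2:
        raise ValueError("need at least 2 units to cluster")
    d = dist.matrix.astype(float).copy()
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    # current distance rows indexed by cluster id
    rows: dict[int, dict[int, float]] = {
        i: {j: d[i, j] for j in range(n) if j != i} for i in range(n)
    }
    merges = np.zeros((n - 1, 4))
    for m in range(n - 1):
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                dab = rows[a][b]
                key = (dab, a, b)
                if best is None or key < best:
                    best = key
        dab, a, b = best  # type: ignore[misc]
        new = n + m
        merges[m] = (a, b, dab, size[a] + size[b])
        size[new] = size[a] + size[b]
        rows[new] = {}
        for x in active:
            if x in (a, b):
                continue
            dx = (size[a] * rows[a][x] + size[b] * rows[b][x]) / size[new]
            rows[new][x] = dx
            rows[x][new] = dx
            del rows[x][a], rows[x][b]
        del rows[a], rows[b]
        active = [x for x in active if x not in (a, b)] + [new]
    return Dendrogram(tuple(dist.units), merges)


def cophenetic_distances(tree: Dendrogram) -> np.ndarray:
    """n x n matrix of the heights at which each leaf pair first merges."""
    n = tree.n
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for m, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        members[n + m] = members.pop(a) + members.pop(b)
    return coph


def cophenetic_correlation(tree: Dendrogram, dist: DistanceMatrix) -> float:
    """Pearson r between original and cophenetic distances.

    Returns ``nan`` when either distance vector is constant (zero
    variance makes the correlation undefined).
    """
    if tuple(tree.leaves) != tuple(dist.units):
        raise ValueError("tree leaves do not match distance units")
    x = dist.condensed()
    y = squareform(cophenetic_distances(tree), checks=False)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select_clustering(
    cover: AbundanceMatrix,
    distance_candidates: Sequence[str] = ("hellinger", "braycurtis", "euclidean"),
    linkage_candidates: Sequence[str] = ("upgma",),
) -> tuple[tuple[str, str], pd.DataFrame]:
    """Pick the (distance, linkage) pair with the highest cophenetic
    correlation; ties break by candidate list order."""
    if not distance_candidates or not linkage_candidates:
        raise ValueError("need at least one candidate of each kind")
    linkages: Mapping[str, Callable[[DistanceMatrix], Dendrogram]] = {"upgma": upgma}
    rows = []
    best = None
    for dname in distance_candidates:
        dm = DISTANCES[dname](cover)
        for lname in linkage_candidates:
            tree = linkages[lname](dm)
            r = cophenetic_correlation(tree, dm)
            rows.append({"distance": dname, "linkage": lname, "cophenetic_r": r})
            score = -np.inf if np.isnan(r) else r
            if best is None or score > best[0]:
                best = (score, (dname, lname))
    return best[1], pd.DataFrame(rows)  # type: ignore[index]


# --- cluster-number diagnostics ------------------------------------------


def silhouette_widths(
    dist: DistanceMatrix, labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Rousseeuw silhouette width per unit and its mean.

    s(i) = (b - a) / max(a, b) with a the mean within-cluster distance
    and b the smallest mean distance to another cluster; singletons get
    s(i) = 0.
    """
    labels = np.asarray(labels)
    if len(labels) != dist.n:
        raise ValueError("labels do not match distance units")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    d = dist.matrix
    s = np.zeros(dist.n)
    for i in range(dist.n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def mantel_cluster_statistic(dist: DistanceMatrix, labels: Sequence[int]) -> float:
    """Pearson r between the distance vector and the binary
    same(0)/different(1) cluster model vector."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    x = dist.condensed()
    n = dist.n
    model = squareform(
        (labels[:, None] != labels[None, :]).astype(float), checks=False
    )
    if np.ptp(x) == 0 or np.ptp(model) == 0:
        return float("nan")
    return float(np.corrcoef(x, model)[0, 1])


def choose_k(
    tree: Dendrogram, dist: DistanceMatrix, k_max: int = 8
) -> tuple[int, pd.DataFrame]:
    """Cut the dendrogram at k = 2..k_max; return the k with the best
    mean silhouette (ties -> smaller k) and the diagnostics table
    (mean silhouette and Mantel r per k)."""
    if not 2 <= k_max <= dist.n - 1:
        raise ValueError("k_max must satisfy 2 <= k_max <= n - 1")
    rows = []
    for k in range(2, k_max + 1):
        labels = tree.cut(k)
        if len(np.unique(labels)) < 2:
            continue
        _, mean_s = silhouette_widths(dist, labels)
        r = mantel_cluster_statistic(dist, labels)
        rows.append({"k": k, "mean_silhouette": mean_s, "mantel_r": r})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    # idxmax takes the first maximum, i.e. the smallest k on ties
    return best, table


# --- NMDS ----------------------------------------------------------------


@dataclass(frozen=True)
class Ordination:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    seed: int


def _stress1(d_config: np.ndarray, d_hat: np.ndarray) -> float:
    denom = (d_config**2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d_config - d_hat) ** 2).sum() / denom))


def nmds(
    dist: DistanceMatrix,
    n_dim: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ordination:
    """Non-metric multidimensional scaling by iterated majorisation.

    Each random start alternates a monotone (isotonic) regression of
    configuration distances on the rank order of the input
    dissimilarities with a Guttman-transform update, and minimises
    Kruskal stress-1.  The best-stress solution over the starts is
    returned; the stress of a run never exceeds that of its initial
    configuration.
    """
    from sklearn.isotonic import IsotonicRegression

    n = dist.n
    dvec = dist.condensed()
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression()
    root = np.random.SeedSequence(seed)

    # classical-scaling (principal-coordinate) start plus random starts
    G = _gower_centered(dist.matrix)
    evals, evecs = np.linalg.eigh(G)
    idx = np.argsort(evals)[::-1][:n_dim]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))
    inits: list[np.ndarray] = [pcoa]
    for child in root.spawn(max(n_starts - 1, 0)):
        rng = np.random.default_rng(child)
        inits.append(rng.normal(size=(n, n_dim)))

    best: tuple[float, np.ndarray, bool] | None = None
    for X in inits:
        X = X.copy()
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            dc = pdist(X)
            # monotone regression in the order of the input distances
            dhat = np.empty_like(dc)
            dhat[order] = iso.fit_transform(np.arange(len(dvec)), dc[order])
            stress = _stress1(dc, dhat)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform toward the fitted disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dc > 0, dhat / dc, 0.0)
            B = -squareform(ratio, checks=False)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        dc = pdist(X)
        dhat = np.empty_like(dc)
        dhat[order] = iso.fit_transform(np.arange(len(dvec)), dc[order])
        stress = _stress1(dc, dhat)
        if best is None or stress < best[0]:
            best = (stress, X, converged)
    stress, X, converged = best  # type: ignore[misc]
    coords = pd.DataFrame(
        X, index=dist.units, columns=[f"NMDS{i + 1}" for i in range(n_dim)]
    )
    return Ordination(coords, float(stress), bool(converged), seed)


# --- PERMANOVA -----------------------------------------------------------


@dataclass(frozen=True)
class PermanovaTable:
    table: pd.DataFrame  # rows: factors (entry order), Residual, Total
    n_permutations: int
    seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _gower_centered(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ a @ J


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Distance-based permutational MANOVA with sequential sums of squares.

    The squared-distance matrix is Gower-centred; each factor's SS is
    the increment in explained trace when its (dummy-coded) design
    columns are added, in the column order of ``factors``.  p-values
    come from free permutation of unit labels with the add-one
    estimator p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    factors = factors.loc[list(dist.units)]
    names = list(factors.columns)
    for name in names:
        if factors[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has a single level")
    n = dist.n
    G = _gower_centered(dist.matrix)
    ss_total = float(np.trace(G))

    # sequential projection hats: intercept, +factor1, +factor1+factor2, ...
    X = np.ones((n, 1))
    hats = [np.ones((n, n)) / n]
    dfs = []
    rank_prev = 1
    for name in names:
        dummies = pd.get_dummies(factors[name], drop_first=False).to_numpy(float)
        X = np.hstack([X, dummies])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(H)
    df_res = n - rank_prev
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    def term_ss(Gm: np.ndarray) -> np.ndarray:
        tr = np.array([float((H * Gm).sum()) for H in hats])
        return tr[1:] - tr[:-1]

    ss = term_ss(G)
    ss_res = ss_total - ss.sum()
    ms_res = ss_res / df_res
    F = (ss / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ssp = term_ss(Gp)
        resp = ss_total - ssp.sum()
        Fp = (ssp / np.array(dfs)) / (resp / df_res)
        exceed += Fp >= F - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, name in enumerate(names):
        rows.append(
            {
                "term": name,
                "df": dfs[i],
                "SS": ss[i],
                "pseudo_F": F[i],
                "R2": ss[i] / ss_total,
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": ss_res,
            "pseudo_F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "pseudo_F": np.nan,
            "R2": 1.0,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaTable(table, n_perm, seed)


# --- IndVal --------------------------------------------------------------


@dataclass(frozen=True)
class IndValResult:
    """Per-taxon indicator values: A (specificity), B (fidelity),
    IndVal percent per group, best group, permutation p, and the
    characteristic flag (IndVal >= threshold and p < alpha)."""

    table: pd.DataFrame
    n_permutations: int
    seed: int
    threshold: float


def _indval_components(
    x: np.ndarray, groups: np.ndarray, uniq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """A and B matrices (taxa x groups) of the Dufrene-Legendre IndVal."""
    means = np.stack([x[groups == g].mean(axis=0) for g in uniq], axis=1)
    occ = np.stack([(x[groups == g] > 0).mean(axis=0) for g in uniq], axis=1)
    tot = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(tot > 0, means / tot, 0.0)
    return A, occ


def indval(
    cover: AbundanceMatrix | pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    threshold: float = 70.0,
    alpha: float = 0.05,
) -> IndValResult:
    """Dufrene-Legendre indicator-species analysis.

    A_tg = mean abundance of taxon t in group g over the sum of its
    group means (specificity); B_tg = share of group-g plots occupied
    (fidelity); IndVal_tg = 100 A B.  Each taxon's statistic is its
    maximum-group IndVal; significance by free permutation of the group
    labels with the add-one estimator.
    """
    df = cover.df if isinstance(cover, AbundanceMatrix) else cover
    groups = np.asarray(groups)
    if len(groups) != df.shape[0]:
        raise ValueError("groups must align with cover rows")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    x = df.to_numpy(dtype=float)
    empty = x.sum(axis=0) == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} taxa absent from every plot",
            stacklevel=2,
        )
        df = df.loc[:, ~empty]
        x = x[:, ~empty]

    A, B = _indval_components(x, groups, uniq)
    iv = 100.0 * A * B
    best_idx = iv.argmax(axis=1)
    stat = iv.max(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(df.columns))
    for _ in range(n_perm):
        gp = rng.permutation(groups)
        Ap, Bp = _indval_components(x, gp, uniq)
        exceed += (100.0 * Ap * Bp).max(axis=1) >= stat - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    out = pd.DataFrame(
        {
            "taxon_id": df.columns,
            "best_group": uniq[best_idx],
            "indval_percent": stat,
            "A": A[np.arange(len(best_idx)), best_idx],
            "B": B[np.arange(len(best_idx)), best_idx],
            "p": pvals,
        }
    ).set_index("taxon_id")
    for g_i, g in enumerate(uniq):
        out[f"indval_{g}"] = iv[:, g_i]
    out["characteristic"] = (out["indval_percent"] >= threshold) & (out["p"] < alpha)
    return IndValResult(out, n_perm, seed, threshold)
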