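"""Alpha and beta diversity for stratified-lake amplicon time series.

Alpha diversity is observed OTU richness on rarefied counts.  Beta
diversity supports Bray-Curtis, Jaccard (on presence/absence) and three
UniFrac variants computed from a rooted phylogeny:

* unweighted UniFrac: branch length unique to one sample divided by the
  total branch length observed in either;
* weighted UniFrac (raw): sum over branches of b_i * |p_i^A - p_i^B|,
  where p_i is the proportion of a sample's reads descending from branch
  i (unbounded above);
* weighted UniFrac (normalized): the raw sum divided by
  sum_j d_j (p_j^A + p_j^B) over leaves at root distance d_j, which
  bounds the distance in [0, 1].

Ordination is classical principal-coordinate analysis (Gower centering of
-D^2/2); group structure is tested by PERMANOVA (distance-based sums of
squares, pseudo-F, permutation p-value) and pairwise differences in
scalar summaries (richness, dispersion) by exact Wilcoxon rank tests with
Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as _stats

from .model import OtuTable, relative_abundance

__all__ = [
    "DistanceMatrix", "OrdinationResult", "PermanovaResult",
    "richness", "rarefaction_curves", "beta_diversity", "pcoa",
    "permanova", "pairwise_group_test", "within_group_dispersion",
    "time_decay", "zscore_by_year", "BETA_METRICS",
]

BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac",
                "weighted_unifrac_raw", "weighted_unifrac_norm")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if d.size and d.min() < 0:
            raise ValueError("negative distances")
        object.__setattr__(self, "data", d)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.data[i, j]

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray        # samples x retained axes
    eigenvalues: np.ndarray        # retained (positive), descending
    proportion_explained: np.ndarray
    labels: tuple[str, ...]


@dataclass(frozen=True)
class PermanovaResult:
    r2: float
    F: float
    p: float
    n_perm: int


def richness(table: OtuTable) -> np.ndarray:
    """Observed richness: OTUs with count > 0, per sample."""
    return (table.counts > 0).sum(axis=1)


def rarefaction_curves(table: OtuTable, depths, reps: int = 10, *,
                       seed: int) -> pd.DataFrame:
    """Mean richness of ``reps`` subsamples without replacement per depth.

    Entries where depth exceeds the sample total are NaN (undefined).
    Returns a samples x depths DataFrame.
    """
    rng = np.random.default_rng(seed)
    depths = list(depths)
    totals = table.sample_totals()
    out = np.full((table.n_samples, len(depths)), np.nan)
    for i in range(table.n_samples):
        row = table.counts[i]
        for j, depth in enumerate(depths):
            if depth > totals[i]:
                continue
            if depth == totals[i]:
                out[i, j] = (row > 0).sum()
                continue
            acc = 0
            for _ in range(reps):
                sub = rng.multivariate_hypergeometric(row, depth)
                acc += int((sub > 0).sum())
            out[i, j] = acc / reps
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def _tree_structures(tree, otu_ids):
    """Branch incidence of a rooted tree against the table's OTU axis.

    Returns (L, b, depth): L is an (n_otus x n_branches) 0/1 matrix where
    L[j, e] = 1 iff leaf j descends through branch e; b the branch
    lengths; depth the root-to-leaf distance per OTU (0 for OTUs absent
    from the tree, which is only legal if they have zero counts).
    """
    otu_index = {o: j for j, o in enumerate(otu_ids)}
    leaf_map = {}
    for leaf in tree.tips():
        if leaf.name in otu_index:
            leaf_map[leaf] = otu_index[leaf.name]
    branches = []   # (length, member otu indices)
    below = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            below[node] = [leaf_map[node]] if node in leaf_map else []
        else:
            members = []
            for child in node.children:
                members.extend(below[child])
            below[node] = members
        if not node.is_root():
            length = node.length if node.length is not None else 0.0
            branches.append((float(length), below[node]))
    n_otus = len(otu_ids)
    L = np.zeros((n_otus, len(branches)), dtype=np.float64)
    b = np.empty(len(branches))
    for e, (length, members) in enumerate(branches):
        b[e] = length
        L[members, e] = 1.0
    depth = L @ b  # root distance of each leaf; 0 for absent OTUs
    in_tree = np.zeros(n_otus, dtype=bool)
    for j in leaf_map.values():
        in_tree[j] = True
    return L, b, depth, in_tree


def beta_diversity(table: OtuTable, metric: str,
                   tree=None) -> DistanceMatrix:
    """Pairwise sample distances under one of :data:`BETA_METRICS`.

    UniFrac variants require a rooted tree (scikit-bio ``TreeNode``) whose
    leaves cover every OTU with a nonzero count.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from "
                         f"{BETA_METRICS}")
    labels = tuple(table.sample_ids)
    X = table.counts.astype(float)
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    else:
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        L, b, depth, in_tree = _tree_structures(tree, table.otu_ids)
        present = table.counts.sum(axis=0) > 0
        missing = [o for o, p, t in zip(table.otu_ids, present, in_tree)
                   if p and not t]
        if missing:
            raise ValueError(
                f"OTUs with counts missing from the tree: {missing[:10]}")
        A = relative_abundance(table)
        P = A @ L                         # samples x branches proportions
        if metric == "weighted_unifrac_raw":
            d = pdist(P, metric="cityblock", w=b)
        elif metric == "weighted_unifrac_norm":
            raw = squareform(pdist(P, metric="cityblock", w=b), checks=False)
            D_i = A @ depth               # sum_j d_j p_ij per sample
            denom = D_i[:, None] + D_i[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                full = np.where(denom > 0, raw / denom, 0.0)
            np.fill_diagonal(full, 0.0)
            return DistanceMatrix(labels, full)
        else:  # unweighted_unifrac
            B = (P > 0).astype(float)
            W = (B * b) @ B.T             # shared branch length
            u = B @ b                     # observed branch length per sample
            union = u[:, None] + u[None, :] - W
            xor = u[:, None] + u[None, :] - 2 * W
            with np.errstate(invalid="ignore", divide="ignore"):
                full = np.where(union > 0, xor / union, 0.0)
            full = (full + full.T) / 2
            np.fill_diagonal(full, 0.0)
            return DistanceMatrix(labels, np.clip(full, 0.0, None))
    return DistanceMatrix(labels, squareform(d, checks=False))


def pcoa(dm: DistanceMatrix, eig_tolerance: float = 1e-10,
         ) -> OrdinationResult:
    """Classical scaling (PCoA): eigendecomposition of Gower-centered
    -D^2/2.  Axes with eigenvalues below tolerance (including all negative
    ones) are discarded; proportion explained is over positive eigenvalues
    only.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    D2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(eig_tolerance, abs(eigvals[0]) * 1e-12) if n else eig_tolerance
    keep = eigvals > tol
    pos_sum = eigvals[eigvals > 0].sum()
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep] * 0.0
    return OrdinationResult(coordinates=coords, eigenvalues=eigvals[keep],
                            proportion_explained=prop, labels=dm.labels)


def _ss_within(D2: np.ndarray, onehot: np.ndarray,
               sizes: np.ndarray) -> float:
    # sum_g (1/n_g) sum_{i<j in g} d^2 ; the quadratic form counts each
    # unordered pair twice, hence the factor 2 in the denominator
    per_group = np.einsum("ig,ij,jg->g", onehot, D2, onehot)
    return float((per_group / (2.0 * sizes)).sum())


def permanova(dm: DistanceMatrix, groups, n_perm: int | str = 999, *,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions the total sum of squared distances into between- and
    within-group components, forms the pseudo-F statistic, and estimates
    the p-value by unrestricted permutation of sample labels with the
    (count + 1) / (n_perm + 1) estimator.  ``n_perm="exact"`` enumerates
    all label permutations (feasible only for small n).
    """
    labels = list(groups)
    n = len(dm.labels)
    if len(labels) != n:
        raise ValueError("groups must align with distance matrix labels")
    uniq = sorted(set(labels))
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    code = np.array([uniq.index(g) for g in labels])
    sizes = np.bincount(code, minlength=a).astype(float)
    if np.any(sizes == 0):
        raise ValueError("empty group")
    D2 = dm.data ** 2
    ss_total = D2.sum() / (2.0 * n)

    onehot = np.zeros((n, a))
    onehot[np.arange(n), code] = 1.0
    ss_within = _ss_within(D2, onehot, sizes)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        warnings.warn("within-group sum of squares is zero; F is infinite")
        F_obs = np.inf
    else:
        F_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    if n_perm == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            ssw = _ss_within(D2, onehot[list(perm)], sizes)
            f = (np.inf if ssw <= 0
                 else ((ss_total - ssw) / (a - 1)) / (ssw / (n - a)))
            count += f >= F_obs
            total += 1
        return PermanovaResult(r2=r2, F=F_obs, p=count / total, n_perm=total)

    if seed is None:
        raise ValueError("seed is required for permutation testing")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        ssw = _ss_within(D2, onehot[perm], sizes)
        f = (np.inf if ssw <= 0
             else ((ss_total - ssw) / (a - 1)) / (ssw / (n - a)))
        count += f >= F_obs
    p = (count + 1) / (int(n_perm) + 1)
    return PermanovaResult(r2=r2, F=F_obs, p=p, n_perm=int(n_perm))


def _rank_test(x, y, paired: bool) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length groups")
        diffs = x - y
        if np.all(diffs == 0):
            return 1.0
        mode = ("exact" if len(x) <= 30 and len(np.unique(np.abs(diffs)))
                == np.count_nonzero(diffs) else "approx")
        return float(_stats.wilcoxon(x, y, alternative="two-sided",
                                     method=mode).pvalue)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(x), len(y)) <= 30) \
        else "asymptotic"
    return float(_stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=method).pvalue)


def pairwise_group_test(values, groups, paired: bool = False,
                        correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise Wilcoxon tests between groups of a scalar summary.

    Unpaired groups use the exact two-sided rank-sum test (normal
    approximation for large or tied samples); ``paired=True`` uses the
    signed-rank test and requires aligned equal-length groups.  Adjusted
    p-values are Bonferroni: min(1, p * number of pairs).
    """
    values = np.asarray(values, dtype=float)
    labels = list(groups)
    uniq = sorted(set(labels))
    by_group = {g: values[[i for i, l in enumerate(labels) if l == g]]
                for g in uniq}
    pairs = list(itertools.combinations(uniq, 2))
    rows = []
    for g1, g2 in pairs:
        p = _rank_test(by_group[g1], by_group[g2], paired)
        rows.append({"group1": g1, "group2": g2, "p": p})
    df = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    if correction == "bonferroni":
        df["adjusted_p"] = np.minimum(1.0, df["p"] * len(pairs))
    elif correction in (None, "none"):
        df["adjusted_p"] = df["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def within_group_dispersion(dm: DistanceMatrix, groups) -> dict:
    """All within-group pairwise distances, per group.

    A group of n_g samples yields n_g (n_g - 1) / 2 distances; groups of
    size < 2 yield an empty array.
    """
    labels = list(groups)
    out = {}
    for g in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == g]
        out[g] = np.array([dm.data[i, j]
                           for i, j in itertools.combinations(idx, 2)])
    return out


def time_decay(dm: DistanceMatrix, metadata,
               site_key=lambda m: (m.lake, m.layer)) -> pd.DataFrame:
    """Within-site (time difference, distance) pairs for time-decay plots.

    ``metadata`` maps sample_id -> SampleMetadata (or is an iterable of
    SampleMetadata).  No aggregation or curve fitting is applied.
    """
    if not isinstance(metadata, dict):
        metadata = {m.sample_id: m for m in metadata}
    missing = [s for s in dm.labels if s not in metadata]
    if missing:
        raise ValueError(f"samples without metadata/date: {missing[:10]}")
    rows = []
    for i, j in itertools.combinations(range(len(dm.labels)), 2):
        mi, mj = metadata[dm.labels[i]], metadata[dm.labels[j]]
        if site_key(mi) != site_key(mj):
            continue
        rows.append({"site": str(site_key(mi)),
                     "sample1": dm.labels[i], "sample2": dm.labels[j],
                     "dt_days": abs((mi.date - mj.date).days),
                     "distance": dm.data[i, j]})
    return pd.DataFrame(rows, columns=["site", "sample1", "sample2",
                                       "dt_days", "distance"])


def zscore_by_year(values, years) -> np.ndarray:
    """Z-score a series independently within each year.

    Uses the sample standard deviation (ddof=1); a year whose values are
    constant maps to zeros by convention; a year with a single
    observation is an error (its SD is undefined).
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(list(years))
    out = np.empty_like(values)
    for y in np.unique(years):
        mask = years == y
        if mask.sum() < 2:
            raise ValueError(f"year {y} has fewer than 2 observations")
        sd = values[mask].std(ddof=1)
        mu = values[mask].mean()
        out[mask] = 0.0 if sd == 0 else (values[mask] - mu) / sd
    return out
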