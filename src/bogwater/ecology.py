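"""Core community, membership overlap, indicator taxa and lifestyles.

The questions these tools answer for a multi-lake amplicon time series:

* Which taxa are *core* — present in at least 90% of a group of samples,
  regardless of abundance?
* How does community membership overlap between mixing regimes (a
  presence/absence Venn decomposition)?
* Which taxa *indicate* a mixing regime?  The statistic is a
  group-equalized point-biserial correlation: each sample is weighted so
  every group contributes equal mass, and the statistic is the weighted
  Pearson correlation between a taxon's abundance and 0/1 group
  membership.  It is signed, so it captures both positive and negative
  habitat preference; significance comes from label permutations.
* What *lifestyle* does a lineage follow — persistence (occupancy
  fraction), mean relative abundance when present, and coefficient of
  variation of abundance?
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import OtuTable

__all__ = ["IndicatorResult", "LifestyleProfile", "core_taxa",
           "aggregate_rank", "membership_overlap", "indicator_analysis",
           "lifestyle"]


@dataclass(frozen=True)
class IndicatorResult:
    taxon_id: str
    rank: str
    target_group: str
    stat: float
    p: float
    adjusted_p: float


@dataclass(frozen=True)
class LifestyleProfile:
    lineage: str
    group: str
    persistence: float
    mean_abundance_present: float
    cv: float


def core_taxa(table: OtuTable, occupancy: float = 0.90) -> set[str]:
    """OTUs present (count > 0) in at least ``occupancy`` of samples.

    The threshold is inclusive: presence in exactly 90% of samples
    qualifies at the default.
    """
    if not 0 < occupancy <= 1:
        raise ValueError(f"occupancy must be in (0, 1], got {occupancy}")
    if table.n_samples == 0:
        raise ValueError("core detection needs at least one sample")
    frac = (table.counts > 0).mean(axis=0)
    return {o for o, f in zip(table.otu_ids, frac) if f >= occupancy}


def aggregate_rank(table: OtuTable, assignments, rank: str) -> OtuTable:
    """Sum OTU counts into taxa at one rank.

    OTUs unclassified at that rank (or classified in a vocabulary that
    lacks it) are excluded, so output totals can be below input totals.
    ``rank="otu"`` is the identity.
    """
    if rank == "otu":
        return OtuTable(table.counts.copy(), table.sample_ids, table.otu_ids)
    label_of = {}
    for a in assignments:
        label = a.label_at(rank)
        if label is not None and label != "unclassified":
            label_of[a.otu_id] = label
    taxa = sorted(set(label_of.values()))
    taxon_index = {t: i for i, t in enumerate(taxa)}
    out = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    for j, otu in enumerate(table.otu_ids):
        label = label_of.get(otu)
        if label is not None:
            out[:, taxon_index[label]] += table.counts[:, j]
    return OtuTable(out, table.sample_ids, taxa)


def membership_overlap(table: OtuTable, grouping) -> dict:
    """Presence/absence Venn region counts over sample categories.

    ``grouping`` maps sample_id -> category.  An OTU is present in a
    category if it has a nonzero count in at least one of its samples;
    the returned dict maps each nonempty frozenset of categories to the
    number of OTUs present in exactly those categories.  Region counts
    sum to the number of OTUs present anywhere.
    """
    unmapped = [s for s in table.sample_ids if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a category: {unmapped[:10]}")
    cats = sorted({grouping[s] for s in table.sample_ids})
    presence = {}
    for c in cats:
        idx = [i for i, s in enumerate(table.sample_ids)
               if grouping[s] == c]
        presence[c] = (table.counts[idx] > 0).any(axis=0)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(cats) + 1):
        for combo in itertools.combinations(cats, r):
            regions[frozenset(combo)] = 0
    for j in range(table.n_otus):
        members = frozenset(c for c in cats if presence[c][j])
        if members:
            regions[members] += 1
    return regions


def _augmented_rows(table: OtuTable, assignments, ranks):
    """Stack raw OTUs plus rank-aggregated taxa into one abundance matrix."""
    blocks = [table.counts.astype(float)]
    row_ids = [("otu", o) for o in table.otu_ids]
    for rank in ranks:
        agg = aggregate_rank(table, assignments, rank)
        if agg.n_otus:
            blocks.append(agg.counts.astype(float))
            row_ids.extend((rank, t) for t in agg.otu_ids)
    return np.vstack([b.T for b in blocks]), row_ids  # rows x samples


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * m / (rank_pos + 1))
        adj[i] = running
    return adj


def indicator_analysis(table: OtuTable, assignments, groups,
                       min_total: int = 500, n_perm: int = 999, *,
                       seed: int, ranks=None) -> list[IndicatorResult]:
    """Group-equalized indicator analysis across all taxonomic levels.

    Rows are raw OTUs plus taxa aggregated at every rank in ``ranks``
    (default: all ranks seen in the assignments); rows with a data-set
    total below ``min_total`` reads are dropped.  For each row the tested
    patterns are every single group and its complement; the reported
    pattern is the best-correlated one.  The permutation p-value compares
    the observed best statistic against the best statistic under
    ``n_perm`` random relabelings (so the maximization over patterns is
    accounted for), and Benjamini-Hochberg adjusted p-values are reported
    alongside raw ones.
    """
    group_list = list(groups)
    if len(group_list) != table.n_samples:
        raise ValueError("groups must align with table samples")
    uniq = sorted(set(group_list))
    G = len(uniq)
    if G < 2:
        raise ValueError("indicator analysis needs at least 2 groups")
    code = np.array([uniq.index(g) for g in group_list])
    sizes = np.bincount(code, minlength=G)
    if np.any(sizes == 0):
        raise ValueError("empty group")

    if ranks is None:
        seen = []
        for a in assignments:
            for name, _ in a.ranks:
                if name not in seen:
                    seen.append(name)
        ranks = seen
    X, row_ids = _augmented_rows(table, assignments, ranks)
    totals = X.sum(axis=1)
    keep = totals >= min_total
    X, row_ids = X[keep], [r for r, k in zip(row_ids, keep) if k]
    if X.shape[0] == 0:
        return []

    n = table.n_samples
    # group-equalized sample weights: every group contributes mass n/G
    w_of_group = (n / G) / sizes.astype(float)
    W = float(n)
    my = 1.0 / G                       # weighted mean of 0/1 membership
    vary = n * (G - 1) / G ** 2        # weighted SS of membership

    rng = np.random.default_rng(seed)
    perms = np.vstack([np.arange(n)] +
                      [rng.permutation(n) for _ in range(n_perm)])
    codes_p = code[perms]              # (n_perm+1, n)
    w_p = w_of_group[codes_p]          # weights under each relabeling

    M1 = X @ w_p.T                     # (rows, n_perm+1): sum w x
    M2 = (X ** 2) @ w_p.T
    varx = M2 - M1 ** 2 / W
    best = np.full(M1.shape, -np.inf)
    best_pattern = np.zeros(X.shape[0], dtype=int)   # signed pattern index
    for gi in range(G):
        y = (codes_p == gi).astype(float)
        cov = X @ (w_p * y).T - M1 * my
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(varx > 0, cov / np.sqrt(varx * vary), 0.0)
        for signed, stat in ((gi + 1, r), (-(gi + 1), -r)):
            better = stat > best
            best = np.where(better, stat, best)
            best_pattern = np.where(better[:, 0], signed, best_pattern)
    obs = best[:, 0]
    exceed = (best[:, 1:] >= obs[:, None]).sum(axis=1)
    p = (exceed + 1) / (n_perm + 1)
    zero_var = varx[:, 0] <= 0
    obs = np.where(zero_var, 0.0, obs)
    p = np.where(zero_var, 1.0, p)
    adj = _bh_adjust(p)

    results = []
    for i, (rank, taxon) in enumerate(row_ids):
        gi = abs(best_pattern[i]) - 1
        target = uniq[gi] if best_pattern[i] > 0 else f"not:{uniq[gi]}"
        if zero_var[i]:
            target = uniq[0]
        results.append(IndicatorResult(
            taxon_id=taxon, rank=rank, target_group=target,
            stat=float(np.clip(obs[i], -1.0, 1.0)),
            p=float(p[i]), adjusted_p=float(adj[i])))
    return results


def lifestyle(table: OtuTable, assignments, rank: str = "lineage",
              grouping=None, cv_present_only: bool = False,
              ) -> list[LifestyleProfile]:
    """Persistence / mean-abundance-when-present / CV per (taxon, group).

    Abundances are relative to each sample's total reads (the table should
    be rarefied first so depths are comparable).  Persistence is the
    fraction of the group's samples containing the taxon;
    ``mean_abundance_present`` averages over present samples only; the
    coefficient of variation is SD/mean of relative abundance over *all*
    samples of the group by default (``cv_present_only=True`` restricts
    it to present samples).  Taxa absent from every sample of a group are
    omitted for that group.
    """
    if grouping is None:
        grouping = {s: "all" for s in table.sample_ids}
    totals = table.sample_totals().astype(float)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero reads: {bad}")
    agg = aggregate_rank(table, assignments, rank)
    # relative abundance of aggregated taxa w.r.t. whole-sample totals
    R = agg.counts / totals[:, None]
    profiles = []
    for g in sorted({grouping[s] for s in table.sample_ids}):
        idx = [i for i, s in enumerate(table.sample_ids)
               if grouping[s] == g]
        sub = R[idx]
        for j, taxon in enumerate(agg.otu_ids):
            col = sub[:, j]
            present = col > 0
            if not present.any():
                continue
            pool = col[present] if cv_present_only else col
            mean = pool.mean()
            cv = float(pool.std(ddof=0) / mean) if mean > 0 else 0.0
            profiles.append(LifestyleProfile(
                lineage=taxon, group=g,
                persistence=float(present.mean()),
                mean_abundance_present=float(col[present].mean()),
                cv=cv))
    return profiles
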