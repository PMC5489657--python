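"""Post-denoising quality control for amplicon OTU tables.

The pipeline assumes reads have already been denoised into unique
sequences (treated as OTUs).  Four steps remain before diversity
analysis:

1. screen representative sequences for long homopolymer runs, ambiguous
   bases and off-target lengths;
2. remove OTUs seen fewer than 25 times across the whole data set;
3. remove OTUs whose taxonomy hits a blacklist (e.g. chloroplasts);
4. rarefy every sample to a common depth (default 2,500 reads), dropping
   samples with fewer reads.

Rarefaction draws a multivariate-hypergeometric subsample: reads are
subsampled without replacement, mimicking drawing physical reads, and is
reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import OtuTable, TaxonomyAssignment

__all__ = ["FilterReport", "screen_sequences", "filter_rare_otus",
           "remove_blacklisted_taxa", "rarefy"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class FilterReport:
    """What a filtering step removed; fully determines output given input."""

    n_removed_low_abundance: int = 0
    n_removed_screen: int = 0
    n_removed_blacklist: int = 0
    n_samples_dropped: int = 0
    rarefaction_depth: int = 0
    seed: int = 0
    dropped_samples: tuple[str, ...] = ()


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def screen_sequences(seqs, max_homopolymer: int = 8,
                     length_range: tuple[int, int] = (148, 152),
                     allow_ambiguous: bool = False):
    """Split (id, sequence) records into (kept, removed), order preserved.

    A sequence is removed if its longest single-base run exceeds
    ``max_homopolymer``, its length is outside ``length_range``, or it
    contains a non-ACGT character while ``allow_ambiguous`` is false.
    Empty sequences count as removed (incorrect length).
    """
    lo, hi = length_range
    kept, removed = [], []
    for name, seq in seqs:
        seq = seq.upper()
        bad = (len(seq) < lo or len(seq) > hi
               or (len(seq) > 0 and _longest_run(seq) > max_homopolymer)
               or (not allow_ambiguous and (set(seq) - _ACGT)))
        (removed if bad else kept).append((name, seq))
    return kept, removed


def filter_rare_otus(table: OtuTable, min_total: int = 25) -> OtuTable:
    """Drop OTUs with fewer than ``min_total`` reads data-set-wide.

    The threshold is on the whole-table total, not per sample; OTUs with
    total >= min_total are kept.  Idempotent.
    """
    keep = table.otu_totals() >= min_total
    return OtuTable(table.counts[:, keep], table.sample_ids,
                    [o for o, k in zip(table.otu_ids, keep) if k])


def remove_blacklisted_taxa(table: OtuTable, assignments,
                            blacklist) -> OtuTable:
    """Drop OTUs whose assignment carries a blacklisted label at any rank.

    Used to remove off-target amplicons such as chloroplast 16S.  OTUs with
    no labels matching the blacklist (including fully unclassified ones)
    are kept.
    """
    blacklist = set(blacklist)
    by_otu: dict[str, TaxonomyAssignment] = {a.otu_id: a for a in assignments}
    missing = [o for o in table.otu_ids if o not in by_otu]
    if missing:
        raise ValueError(f"OTUs without assignments: {missing[:5]}")
    keep = [o for o in table.otu_ids
            if not (set(by_otu[o].labels) & blacklist)]
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int = 2500, *,
           seed: int) -> tuple[OtuTable, FilterReport]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped and listed in the
    report.  Subsampling is multivariate hypergeometric, so no count can
    exceed its input value and identical (table, depth, seed) give
    identical output.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_rows, kept_ids, dropped = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        if totals[i] == depth:
            kept_rows.append(table.counts[i].copy())
        else:
            kept_rows.append(
                rng.multivariate_hypergeometric(table.counts[i], depth))
        kept_ids.append(sid)
    counts = (np.array(kept_rows, dtype=np.int64)
              if kept_rows else np.zeros((0, table.n_otus), dtype=np.int64))
    out = OtuTable(counts, kept_ids, table.otu_ids)
    report = FilterReport(n_samples_dropped=len(dropped),
                          rarefaction_depth=depth, seed=seed,
                          dropped_samples=tuple(dropped))
    return out, report
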