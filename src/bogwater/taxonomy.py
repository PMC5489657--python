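"""Two-database taxonomy assignment with identity routing.

Freshwater 16S taxonomy is best resolved by a small curated database with
its own rank vocabulary (phylum > lineage > clade > tribe), but that
database only covers known freshwater groups.  The workflow therefore
routes each OTU by sequence identity: OTUs matching a curated freshwater
reference at greater than 98% identity (strict) are classified against
the freshwater database, all others against a comprehensive database
(kingdom > ... > genus).  Classification itself is a k-mer naive-Bayes
bootstrap classifier (the Wang method): the winning taxon maximizes the
summed log conditional probabilities of the query's k-mers, and per-rank
confidence is the fraction of bootstrap replicates (subsamples of 1/8 of
the query k-mers) agreeing with the full-query label; ranks below the
confidence cutoff (default 70%) become "unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import align_identity
from .model import ReferenceDatabase, TaxonomyAssignment

__all__ = ["ClassifierModel", "ClassifierParams", "RoutingResult",
           "train_nb", "classify", "route_otus", "assign_taxonomy"]


@dataclass(frozen=True)
class RoutingResult:
    otu_id: str
    best_pident: float
    routed_to: str  # "freshwater" or "comprehensive"


@dataclass(frozen=True)
class ClassifierParams:
    k: int = 8
    n_boot: int = 100
    conf_cutoff: float = 70.0
    identity_cutoff: float = 98.0
    seed: int = 0


@dataclass
class ClassifierModel:
    """Trained naive-Bayes k-mer model over one reference database."""

    k: int
    rank_names: tuple[str, ...]
    taxa: list[tuple[str, ...]]          # terminal taxon paths, lexicographic
    log_conditionals: np.ndarray         # (n_taxa, 4**k)
    priors: np.ndarray = field(repr=False, default=None)  # (4**k,)


def _kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted distinct k-mer indices; windows with non-ACGT bases skipped."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    vals = np.array([code.get(c, -1) for c in seq.upper()], dtype=np.int64)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = (windows >= 0).all(axis=1)
    idx = (windows[valid] * pw).sum(axis=1)
    return np.unique(idx)


def train_nb(db: ReferenceDatabase, k: int = 8) -> ClassifierModel:
    """Train the Wang-style naive-Bayes model.

    Prior of k-mer w over N training sequences: (n(w) + 0.5) / (N + 1)
    where n(w) counts sequences containing w.  Conditional for taxon t
    with M_t sequences: (m_t(w) + prior(w)) / (M_t + 1).
    """
    paths = sorted(set(db.taxonomies))
    if len(paths) < 2:
        raise ValueError("need at least 2 distinct terminal taxa to train")
    taxon_index = {p: i for i, p in enumerate(paths)}
    vocab = 4 ** k
    n_w = np.zeros(vocab, dtype=np.float64)
    m_tw = np.zeros((len(paths), vocab), dtype=np.float64)
    m_t = np.zeros(len(paths), dtype=np.float64)
    for _, seq, path in db:
        kmers = _kmer_set(seq, k)
        n_w[kmers] += 1.0
        t = taxon_index[path]
        m_tw[t, kmers] += 1.0
        m_t[t] += 1.0
    priors = (n_w + 0.5) / (len(db) + 1.0)
    conditionals = (m_tw + priors[None, :]) / (m_t[:, None] + 1.0)
    return ClassifierModel(k=k, rank_names=db.rank_names, taxa=paths,
                           log_conditionals=np.log(conditionals),
                           priors=priors)


def classify(seq: str, model: ClassifierModel, n_boot: int = 100,
             conf_cutoff: float = 70.0, *, seed,
             otu_id: str = "", source_db: str = "freshwater",
             ) -> TaxonomyAssignment:
    """Classify one sequence; ranks under ``conf_cutoff`` -> unclassified.

    ``seed`` may be an int or a numpy Generator.  Ties in the best-taxon
    score break to the lexicographically first taxon path.  Ranks set to
    "unclassified" are reported with confidence 100 by convention (the
    claim "not confidently classified" is not itself a bootstrap claim).
    """
    kmers = _kmer_set(seq, model.k)
    if kmers.size == 0:
        raise ValueError(f"sequence shorter than k={model.k}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    L = model.log_conditionals
    full_scores = L[:, kmers].sum(axis=1)
    best = int(np.argmax(full_scores))  # first of ties = lexicographic
    best_path = model.taxa[best]

    w = kmers.size
    n_draw = max(1, w // 8)
    draws = rng.integers(0, w, size=(n_boot, n_draw))
    boot_scores = L[:, kmers[draws]].sum(axis=2)      # (n_taxa, n_boot)
    boot_best = np.argmax(boot_scores, axis=0)

    taxa_arr = model.taxa
    n_ranks = len(model.rank_names)
    confidences = np.empty(n_ranks)
    for r in range(n_ranks):
        agree = sum(1 for b in boot_best if taxa_arr[b][r] == best_path[r])
        confidences[r] = 100.0 * agree / n_boot

    labels, confs = [], []
    failed = False
    for r in range(n_ranks):
        if failed or confidences[r] < conf_cutoff:
            failed = True
            labels.append("unclassified")
            confs.append(100.0)
        else:
            labels.append(best_path[r])
            confs.append(float(confidences[r]))
    return TaxonomyAssignment(
        otu_id=otu_id, ranks=tuple(zip(model.rank_names, labels)),
        confidences=tuple(confs), source_db=source_db)


def route_otus(queries, fw_db: ReferenceDatabase,
               cutoff: float = 98.0) -> list[RoutingResult]:
    """Route (id, sequence) queries by best identity against ``fw_db``.

    A query goes to the freshwater database only when its best percent
    identity is strictly greater than ``cutoff``; a best hit of exactly
    the cutoff routes to the comprehensive database.
    """
    if len(fw_db) == 0:
        raise ValueError("freshwater database is empty")
    refs = fw_db.sequences
    out = []
    for otu_id, seq in queries:
        best = max(align_identity(seq, ref) for ref in refs)
        out.append(RoutingResult(
            otu_id=otu_id, best_pident=best,
            routed_to="freshwater" if best > cutoff else "comprehensive"))
    return out


def assign_taxonomy(queries, fw_db: ReferenceDatabase,
                    comp_db: ReferenceDatabase,
                    params: ClassifierParams = ClassifierParams(),
                    ) -> list[TaxonomyAssignment]:
    """Full workflow: route each query, then classify in its database."""
    queries = list(queries)
    if not queries:
        return []
    routing = route_otus(queries, fw_db, cutoff=params.identity_cutoff)
    fw_model = train_nb(fw_db, k=params.k)
    comp_model = train_nb(comp_db, k=params.k)
    streams = np.random.SeedSequence(params.seed).spawn(len(queries))
    out = []
    for (otu_id, seq), route, ss in zip(queries, routing, streams):
        model = fw_model if route.routed_to == "freshwater" else comp_model
        out.append(classify(
            seq, model, n_boot=params.n_boot, conf_cutoff=params.conf_cutoff,
            seed=np.random.default_rng(ss), otu_id=otu_id,
            source_db=route.routed_to))
    return out
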