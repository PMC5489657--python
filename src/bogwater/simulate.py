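"""Synthetic stratified bog-lake communities with known ground truth.

The generator emulates the statistical structure of a multiyear,
multi-lake 16S amplicon survey so that every downstream method can be
exercised against planted truth:

* eight lakes in three mixing regimes, two thermal layers, weekly summer
  sampling over several years;
* regime-structured richness (polymictic < dimictic < meromictic OTU
  pools), with extra unique taxa in meromictic hypolimnia;
* a core set of generalist OTUs present in (nearly) every sample;
* planted indicator OTUs that occur only in lakes of one regime;
* lifestyle archetypes: core generalists (high abundance, low
  variability, full occupancy), conditionally rare taxa (low abundance,
  flickering presence), and bloomer-like taxa (high abundance when
  present, low occupancy);
* interannual composition shifts (a lognormal multiplier per OTU, lake
  and year);
* mixing-event disturbances: on an event date both layers' expected
  compositions are homogenized and only the most abundant fraction of
  taxa survives, crashing richness.

Counts are multinomial draws at a fixed library size from the resulting
expected relative abundances, mimicking compositional sequencing noise;
everything is reproducible from the config seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import (LAKE_REGIMES, OtuTable, ReferenceDatabase,
                    SampleMetadata, TaxonomyAssignment, format_sample_id)

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_timeseries",
           "generate_tree", "generate_refdbs", "sampling_dates",
           "default_mixing_events", "small_config"]

ARCHETYPES = ("core-generalist", "conditionally-rare", "bloomer-like")

#: lognormal base-abundance parameters and per-sample occupancy
#: probability per archetype: (log-mean, log-sd, occupancy)
ARCHETYPE_PARAMS = {
    "core-generalist": (3.0, 0.3, 1.0),
    "conditionally-rare": (0.5, 1.2, 0.35),
    "bloomer-like": (3.5, 1.0, 0.12),
}

_DEPTH_ORDER = ("FB", "CB", "NS", "WS", "TB", "SS", "HK", "MA")
DEFAULT_LAKES = tuple(
    (code, LAKE_REGIMES[code], rank)
    for rank, code in enumerate(_DEPTH_ORDER, start=1))


def sampling_dates(year: int, samples_per_summer: int) -> list[_dt.date]:
    """Weekly sampling dates starting 1 June of ``year``."""
    start = _dt.date(year, 6, 1)
    return [start + _dt.timedelta(days=7 * k)
            for k in range(samples_per_summer)]


def default_mixing_events(years, samples_per_summer):
    """Fall mixing in Trout Bog 2007 and a mid-summer event in North
    Sparkling Bog 2008, when those years are simulated."""
    events = []
    if 2007 in years:
        events.append(("TB", sampling_dates(2007, samples_per_summer)[-1],
                       0.2))
    if 2008 in years:
        mid = samples_per_summer // 2
        events.append(("NS", sampling_dates(2008, samples_per_summer)[mid],
                       0.2))
    return tuple(events)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and effect sizes of the simulated survey."""

    lakes: tuple = DEFAULT_LAKES
    years: tuple = (2005, 2007, 2008, 2009)
    samples_per_summer: int = 10
    layers: tuple = ("epilimnion", "hypolimnion")
    richness_by_regime: dict = field(default_factory=lambda: {
        "polymictic": 500, "dimictic": 800, "meromictic": 1200})
    n_shared_background: int = 200
    n_mero_hypo_extra: int = 100
    n_core: int = 12
    n_indicators_per_regime: int = 10
    archetype_mix: dict = field(default_factory=lambda: {
        "core-generalist": 0.20, "conditionally-rare": 0.65,
        "bloomer-like": 0.15})
    year_effect_sd: float = 0.6
    indicator_occupancy: float = 0.9
    indicator_log_mean: float = 2.5
    indicator_log_sd: float = 0.5
    regime_multiplier: float = 1.0   # 1.0 = indicators are the only regime effect
    library_size: int = 5000
    mixing_events: tuple | None = None
    lineage_size: int = 8
    seed: int = 0

    def __post_init__(self):
        errors = []
        regimes = {r for _, r, _ in self.lakes}
        for r in regimes:
            if r not in self.richness_by_regime:
                errors.append(f"richness_by_regime missing {r!r}")
        mix_sum = sum(self.archetype_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            errors.append(f"archetype_mix sums to {mix_sum}, not 1")
        floor = self.n_core + self.n_shared_background
        for r, size in self.richness_by_regime.items():
            if size < floor:
                errors.append(
                    f"pool for {r} ({size}) smaller than core+shared "
                    f"({floor})")
        for ev in (self.mixing_events or ()):
            lake, date, frac = ev
            if not 0 < frac <= 1:
                errors.append(f"survival_fraction {frac} outside (0, 1]")
            if lake not in {c for c, _, _ in self.lakes}:
                errors.append(f"mixing event lake {lake!r} not simulated")
        if self.library_size < 1:
            errors.append("library_size must be >= 1")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down design (same structure, smaller pools and fewer
    samples) for fast exploratory runs and tests."""
    defaults = dict(
        years=(2007, 2008), samples_per_summer=6,
        richness_by_regime={"polymictic": 120, "dimictic": 190,
                            "meromictic": 280},
        n_shared_background=60, n_mero_hypo_extra=30, n_core=10,
        n_indicators_per_regime=6, library_size=3000, seed=seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclass
class SyntheticTruth:
    """Ledger of planted effects for parameter-recovery tests."""

    core_set: set
    indicator_map: dict          # regime -> list of OTU ids
    archetype_map: dict          # lineage -> archetype
    taxonomy: dict               # otu_id -> (phylum, lineage, clade, tribe)
    year_offsets: dict           # (lake, year) -> per-OTU multipliers
    event_log: list              # (lake, date, survival_fraction, samples)

    def assignments(self) -> list[TaxonomyAssignment]:
        """Oracle freshwater-style assignments for the simulated OTUs."""
        rank_names = ("phylum", "lineage", "clade", "tribe")
        return [TaxonomyAssignment(
                    otu_id=o, ranks=tuple(zip(rank_names, path)),
                    confidences=(100.0,) * 4, source_db="freshwater")
                for o, path in self.taxonomy.items()]


_PHYLA = ("Actinobacteria", "Proteobacteria", "Bacteroidetes",
          "Verrucomicrobia", "Chlorobi")


def _make_taxonomy(otu_ids, lineage_labels):
    """Phylum > lineage > clade > tribe paths; one clade split per
    lineage, tribes shared by pairs of OTUs."""
    taxonomy = {}
    by_lineage: dict[str, list] = {}
    for o, lin in zip(otu_ids, lineage_labels):
        by_lineage.setdefault(lin, []).append(o)
    for li, (lin, members) in enumerate(sorted(by_lineage.items())):
        phylum = _PHYLA[li % len(_PHYLA)]
        half = (len(members) + 1) // 2
        for mi, o in enumerate(members):
            clade = f"{lin}-{'A' if mi < half else 'B'}"
            tribe = f"{clade}{mi // 2 + 1}"
            taxonomy[o] = (phylum, lin, clade, tribe)
    return taxonomy


def simulate_timeseries(config: SyntheticConfig):
    """Simulate the survey; returns (table, metadata, tree, truth)."""
    rng = np.random.default_rng(config.seed)
    regimes = sorted({r for _, r, _ in config.lakes})
    lake_codes = [c for c, _, _ in config.lakes]
    regime_of = {c: r for c, r, _ in config.lakes}

    # ---- build the OTU universe -------------------------------------
    otu_ids: list[str] = []
    lineage_of: list[str] = []
    archetype_of: list[str] = []
    member_mask: dict[tuple[str, str], list[bool]] = {}

    def new_otus(n, prefix):
        start = len(otu_ids)
        for i in range(n):
            otu_ids.append(f"OTU{start + i:05d}")
        return list(range(start, start + n))

    core_idx = new_otus(config.n_core, "core")
    for i, j in enumerate(core_idx):
        lineage_of.append(f"corL{i // config.lineage_size + 1:02d}")
        archetype_of.append("core-generalist")

    indicator_idx: dict[str, list[int]] = {}
    for r in regimes:
        idx = new_otus(config.n_indicators_per_regime, f"ind_{r}")
        indicator_idx[r] = idx
        for i in idx:
            lineage_of.append(f"ind{r[:3].upper()}"
                              f"L{(i - idx[0]) // config.lineage_size + 1:02d}")
            archetype_of.append("conditionally-rare")

    def background_block(n, tag):
        idx = new_otus(n, tag)
        mix_labels = rng.choice(
            ARCHETYPES, size=(len(idx) + config.lineage_size - 1)
            // config.lineage_size,
            p=[config.archetype_mix[a] for a in ARCHETYPES])
        for k, i in enumerate(idx):
            li = k // config.lineage_size
            lineage_of.append(f"{tag}L{li + 1:03d}")
            archetype_of.append(str(mix_labels[li]))
        return idx

    shared_idx = background_block(config.n_shared_background, "bgS")
    extra_idx = {r: background_block(
        config.richness_by_regime[r] - config.n_core
        - config.n_shared_background, f"bg{r[:3].upper()}")
        for r in regimes}
    mero_hypo_idx = (background_block(config.n_mero_hypo_extra, "bgMH")
                     if "meromictic" in regimes else [])

    n_otu = len(otu_ids)
    archetype_of = np.array(archetype_of)
    lineage_of = np.array(lineage_of)

    # base abundance weights and occupancy per OTU
    weight = np.empty(n_otu)
    occupancy = np.empty(n_otu)
    for arch, (mu, sd, occ) in ARCHETYPE_PARAMS.items():
        mask = archetype_of == arch
        weight[mask] = rng.lognormal(mu, sd, size=mask.sum())
        occupancy[mask] = occ
    for r in regimes:
        idx = indicator_idx[r]
        weight[idx] = rng.lognormal(config.indicator_log_mean,
                                    config.indicator_log_sd, size=len(idx))
        occupancy[idx] = config.indicator_occupancy

    # membership: which OTUs can occur in each (lake, layer)
    layer_pref = rng.choice([0, 1], size=n_otu)  # 0 epi, 1 hypo (background)
    for lake in lake_codes:
        r = regime_of[lake]
        for ln, layer in enumerate(("epilimnion", "hypolimnion")):
            mask = np.zeros(n_otu, dtype=bool)
            mask[core_idx] = True
            mask[indicator_idx[r]] = True
            bg = np.array(shared_idx + extra_idx[r], dtype=int)
            mask[bg[layer_pref[bg] == ln]] = True
            if layer == "hypolimnion" and r == "meromictic":
                mask[mero_hypo_idx] = True
            member_mask[(lake, layer)] = mask

    # interannual composition shifts, independent per (lake, year)
    year_mult = {}
    for lake in lake_codes:
        for year in config.years:
            year_mult[(lake, year)] = (
                rng.lognormal(0.0, config.year_effect_sd, size=n_otu)
                if config.year_effect_sd > 0 else np.ones(n_otu))

    events = (config.mixing_events if config.mixing_events is not None
              else default_mixing_events(config.years,
                                         config.samples_per_summer))

    # ---- expected compositions per sample ---------------------------
    metadata: list[SampleMetadata] = []
    expectations: list[np.ndarray] = []
    sample_pos: dict[str, int] = {}
    regime_boost = np.ones(n_otu)
    if config.regime_multiplier != 1.0:
        pass  # applied per-sample below via indicator membership
    for lake in lake_codes:
        r = regime_of[lake]
        for year in config.years:
            ym = year_mult[(lake, year)]
            for date in sampling_dates(year, config.samples_per_summer):
                for layer in config.layers:
                    mask = member_mask[(lake, layer)]
                    present = rng.random(n_otu) < occupancy
                    e = weight * ym * (mask & present)
                    if config.regime_multiplier != 1.0:
                        idx = indicator_idx[r]
                        e[idx] = e[idx] * config.regime_multiplier
                    sid = format_sample_id(lake, layer, date)
                    sample_pos[sid] = len(metadata)
                    metadata.append(SampleMetadata(
                        sample_id=sid, lake=lake, layer=layer, date=date))
                    expectations.append(e)
    E = np.vstack(expectations)

    # ---- mixing-event disturbances ----------------------------------
    event_log = []
    for lake, date, frac in events:
        sids = [m.sample_id for m in metadata
                if m.lake == lake and m.date == date]
        if not sids:
            continue
        rows = [sample_pos[s] for s in sids]
        mixed = E[rows].mean(axis=0)           # water column homogenized
        nz = np.flatnonzero(mixed > 0)
        keep_n = max(1, int(np.ceil(frac * nz.size)))
        order = nz[np.argsort(mixed[nz])[::-1]]
        survivors = order[:keep_n]
        crashed = np.zeros(n_otu)
        crashed[survivors] = mixed[survivors]
        for row in rows:
            E[row] = crashed
        event_log.append((lake, date, frac, tuple(sids)))

    # ---- multinomial read sampling ----------------------------------
    counts = np.empty((len(metadata), n_otu), dtype=np.int64)
    for i in range(len(metadata)):
        total = E[i].sum()
        if total <= 0:  # pathological config; keep sample but empty
            counts[i] = 0
            continue
        counts[i] = rng.multinomial(config.library_size, E[i] / total)
    table = OtuTable(counts, [m.sample_id for m in metadata], otu_ids)

    tree = generate_tree(otu_ids, seed=int(rng.integers(2 ** 31)))
    taxonomy = _make_taxonomy(otu_ids, lineage_of)
    truth = SyntheticTruth(
        core_set={otu_ids[i] for i in core_idx},
        indicator_map={r: [otu_ids[i] for i in indicator_idx[r]]
                       for r in regimes},
        archetype_map={lin: archetype_of[np.argmax(lineage_of == lin)]
                       for lin in np.unique(lineage_of)},
        taxonomy=taxonomy,
        year_offsets=year_mult,
        event_log=event_log)
    return table, metadata, tree, truth


def generate_tree(otu_ids, *, seed: int) -> TreeNode:
    """Random rooted binary tree with exponential branch lengths."""
    otu_ids = list(otu_ids)
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("duplicate OTU ids")
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=o, length=float(rng.exponential(0.1)))
             for o in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)),
                          children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


_BASES = np.array(list("ACGT"))


def _random_seq(rng, length):
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng, seq, n_sub):
    """Substitute exactly ``n_sub`` distinct positions with different bases."""
    seq = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[int(rng.integers(3))]
    return "".join(seq)


def generate_refdbs(n_fw_taxa: int = 12, n_comp_taxa: int = 12,
                    divergence: float = 0.15, fragment_length: int = 150,
                    ref_length: int = 1200, queries_per_ref: int = 3,
                    error_rates=(0.0, 0.01, 0.05), *, seed: int):
    """Reference databases plus routed queries with an answer key.

    Freshwater references form a phylum > lineage > clade > tribe
    hierarchy where sibling terminal taxa differ at ``divergence`` of
    positions; comprehensive references are independent random sequences.
    Queries are ``fragment_length`` slices of freshwater references with
    an exact number of substitutions per configured error rate, so the
    true percent identity (and hence the correct routing side of the 98%
    cutoff) is known by construction.  Returns
    (fw_db, comp_db, queries, answer_key DataFrame).
    """
    if not 0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    rng = np.random.default_rng(seed)

    fw_records = []
    n_lineages = max(1, (n_fw_taxa + 3) // 4)
    t = 0
    while t < n_fw_taxa:
        lin = f"fwL{len(fw_records) // 4 + 1:02d}"
        lin_anc = _random_seq(rng, ref_length)
        phylum = _PHYLA[(t // 4) % len(_PHYLA)]
        for c in range(min(4, n_fw_taxa - t)):
            clade = f"{lin}-{'AB'[c % 2]}"
            tribe = f"{clade}{c + 1}"
            seq = _mutate(rng, lin_anc, int(round(divergence * ref_length)))
            fw_records.append((f"FW{t:03d}", seq,
                               (phylum, lin, clade, tribe)))
            t += 1
    fw_db = ReferenceDatabase(fw_records,
                              ("phylum", "lineage", "clade", "tribe"))

    comp_ranks = ("kingdom", "phylum", "class", "order", "family", "genus")
    comp_records = []
    for t in range(n_comp_taxa):
        path = ("Bacteria", f"cphy{t // 8 + 1}", f"ccls{t // 4 + 1}",
                f"cord{t // 2 + 1}", f"cfam{t + 1}", f"cgen{t + 1}")
        comp_records.append((f"CP{t:03d}", _random_seq(rng, ref_length),
                             path))
    comp_db = ReferenceDatabase(comp_records, comp_ranks)

    queries, key_rows = [], []
    q = 0
    for seq_id, seq, path in fw_records:
        for k in range(queries_per_ref):
            rate = error_rates[k % len(error_rates)]
            off = int(rng.integers(0, ref_length - fragment_length + 1))
            frag = seq[off:off + fragment_length]
            n_sub = int(round(rate * fragment_length))
            frag = _mutate(rng, frag, n_sub) if n_sub else frag
            pident = 100.0 * (fragment_length - n_sub) / fragment_length
            qid = f"Q{q:04d}"
            q += 1
            queries.append((qid, frag))
            key_rows.append({
                "query_id": qid, "source_ref": seq_id,
                "true_taxonomy": ";".join(path), "error_rate": rate,
                "planted_pident": pident,
                "true_route": ("freshwater" if pident > 98.0
                               else "comprehensive")})
    key = pd.DataFrame(key_rows)
    return fw_db, comp_db, queries, key
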