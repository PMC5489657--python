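"""Core domain types for bog-lake amplicon surveys.

The survey design covers eight humic bog lakes in northern Wisconsin,
each sampled in two thermal layers (epilimnion / hypolimnion) at roughly
weekly intervals during summer stratification, over multiple years.  Each
lake belongs to one of three water-column mixing regimes:

* polymictic  — mixes many times per year,
* dimictic    — mixes twice per year (spring and fall),
* meromictic  — no recorded mixing events.

Everything downstream (richness comparisons, UniFrac ordination,
core-community and indicator analysis) operates on an :class:`OtuTable`
(integer read counts, samples x OTUs) plus per-sample metadata.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LAKE_REGIMES",
    "LAKE_CODES",
    "LAYERS",
    "REGIMES",
    "OtuTable",
    "SampleMetadata",
    "TaxonomyAssignment",
    "ReferenceDatabase",
    "SampleIdError",
    "mixing_regime",
    "parse_sample_id",
    "format_sample_id",
    "relative_abundance",
]

#: Mixing regime of each study lake (Forestry Bog, Crystal Bog, North
#: Sparkling Bog, West Sparkling Bog, Trout Bog, South Sparkling Bog,
#: Hell's Kitchen, Mary Lake).
LAKE_REGIMES: dict[str, str] = {
    "FB": "polymictic",
    "CB": "polymictic",
    "NS": "dimictic",
    "WS": "polymictic",
    "TB": "dimictic",
    "SS": "dimictic",
    "HK": "meromictic",
    "MA": "meromictic",
}

LAKE_CODES = tuple(LAKE_REGIMES)
LAYERS = ("epilimnion", "hypolimnion", "unsplit")
REGIMES = ("polymictic", "dimictic", "meromictic")

_LAYER_LETTER = {"E": "epilimnion", "H": "hypolimnion", "U": "unsplit"}
_LETTER_OF_LAYER = {v: k for k, v in _LAYER_LETTER.items()}

_MONTHS = ("JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC")
_MONTH_NUM = {m: i + 1 for i, m in enumerate(_MONTHS)}

_ID_RE = re.compile(
    r"^(?P<lake>[A-Z]{2})(?P<layer>[A-Z])"
    r"(?P<day>\d{2})(?P<mon>[A-Z]{3})(?P<yy>\d{2})"
    r"(?:\.(?P<rep>R\d+))?$"
)


class SampleIdError(ValueError):
    """A sample identifier does not follow the site-code grammar."""


def mixing_regime(lake: str) -> str:
    """Mixing regime of a study lake code (e.g. ``TB`` -> ``dimictic``)."""
    try:
        return LAKE_REGIMES[lake]
    except KeyError:
        raise SampleIdError(f"unknown lake code: {lake!r}") from None


def parse_sample_id(sample_id: str) -> tuple[str, str, _dt.date, str]:
    """Decompose a sample identifier into (lake, layer, date, replicate).

    Identifiers follow the grammar ``LL + layer-letter + DDMMMYY`` with an
    optional ``.R<digit>`` replicate suffix, e.g. ``TBE05JUL07`` is the
    Trout Bog epilimnion sampled 2007-07-05 and ``MAU12JUN05.R2`` is the
    second replicate of an unsplit Mary Lake water column from 2005-06-12.
    Two-digit years map into 2000-2099.
    """
    m = _ID_RE.match(sample_id)
    if m is None:
        raise SampleIdError(f"malformed sample id: {sample_id!r}")
    lake = m.group("lake")
    if lake not in LAKE_REGIMES:
        raise SampleIdError(f"unknown lake code: {lake!r} in {sample_id!r}")
    layer_letter = m.group("layer")
    if layer_letter not in _LAYER_LETTER:
        raise SampleIdError(
            f"unknown layer letter: {layer_letter!r} in {sample_id!r}")
    mon = m.group("mon")
    if mon not in _MONTH_NUM:
        raise SampleIdError(f"unknown month token: {mon!r} in {sample_id!r}")
    try:
        date = _dt.date(2000 + int(m.group("yy")),
                        _MONTH_NUM[mon], int(m.group("day")))
    except ValueError as exc:
        raise SampleIdError(f"invalid calendar date in {sample_id!r}: {exc}")
    rep = m.group("rep") or ""
    return lake, _LAYER_LETTER[layer_letter], date, rep


def format_sample_id(lake: str, layer: str, date: _dt.date,
                     replicate: str = "") -> str:
    """Inverse of :func:`parse_sample_id` on valid field tuples."""
    if lake not in LAKE_REGIMES:
        raise SampleIdError(f"unknown lake code: {lake!r}")
    if layer not in _LETTER_OF_LAYER:
        raise SampleIdError(f"unknown layer: {layer!r}")
    sid = (f"{lake}{_LETTER_OF_LAYER[layer]}{date.day:02d}"
           f"{_MONTHS[date.month - 1]}{date.year % 100:02d}")
    if replicate:
        sid += f".{replicate}"
    return sid


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample provenance: lake, layer, date and derived fields."""

    sample_id: str
    lake: str
    layer: str
    date: _dt.date
    replicate: str = ""
    mixing_regime: str = field(init=False)
    year: int = field(init=False)

    def __post_init__(self) -> None:
        if self.lake not in LAKE_REGIMES:
            raise SampleIdError(f"unknown lake code: {self.lake!r}")
        if self.layer not in LAYERS:
            raise SampleIdError(f"unknown layer: {self.layer!r}")
        object.__setattr__(self, "mixing_regime", LAKE_REGIMES[self.lake])
        object.__setattr__(self, "year", self.date.year)

    @classmethod
    def from_sample_id(cls, sample_id: str) -> "SampleMetadata":
        lake, layer, date, rep = parse_sample_id(sample_id)
        return cls(sample_id=sample_id, lake=lake, layer=layer,
                   date=date, replicate=rep)


class OtuTable:
    """Integer read-count matrix, samples x OTUs.

    ``counts[i, j]`` is the number of reads of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``.  Identifiers are unique and aligned with the matrix
    axes; every entry is a non-negative integer.
    """

    __slots__ = ("counts", "sample_ids", "otu_ids",
                 "_sample_index", "_otu_index")

    def __init__(self, counts, sample_ids, otu_ids):
        counts = np.asarray(counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
        counts = counts.astype(np.int64, copy=False).reshape(
            len(sample_ids), len(otu_ids))
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        sample_ids = list(map(str, sample_ids))
        otu_ids = list(map(str, otu_ids))
        for name, ids in (("sample", sample_ids), ("OTU", otu_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dup}")
        self.counts = counts
        self.sample_ids = sample_ids
        self.otu_ids = otu_ids
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._otu_index = {o: j for j, o in enumerate(otu_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def otu_index(self, otu_id: str) -> int:
        return self._otu_index[otu_id]

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(self.counts[idx], list(sample_ids), self.otu_ids)

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self._otu_index[o] for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, list(otu_ids))

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts[:, keep], self.sample_ids,
                        [o for o, k in zip(self.otu_ids, keep) if k])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.otu_ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, OtuTable)
                and self.sample_ids == other.sample_ids
                and self.otu_ids == other.otu_ids
                and np.array_equal(self.counts, other.counts))

    def __repr__(self) -> str:
        return f"<OtuTable {self.n_samples} samples x {self.n_otus} OTUs>"


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample read proportions; each row sums to 1.

    Raises if any sample has zero total reads (a proportion is undefined
    there); callers should drop or flag such samples first.
    """
    totals = table.sample_totals()
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"samples with zero reads: {bad}")
    return table.counts / totals[:, None]


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Multi-rank classification of one OTU with per-rank confidence.

    ``ranks`` is an ordered (coarse to fine) tuple of (rank_name, label)
    pairs; the freshwater vocabulary runs phylum > lineage > clade > tribe,
    the comprehensive vocabulary kingdom > ... > genus.  ``confidences``
    are bootstrap percentages aligned with ``ranks``.  Once a rank is
    "unclassified" every finer rank is too.
    """

    otu_id: str
    ranks: tuple[tuple[str, str], ...]
    confidences: tuple[float, ...]
    source_db: str  # "freshwater" or "comprehensive"

    def __post_init__(self) -> None:
        if len(self.ranks) != len(self.confidences):
            raise ValueError("ranks and confidences must align")
        if self.source_db not in ("freshwater", "comprehensive"):
            raise ValueError(f"bad source_db: {self.source_db!r}")
        seen_unclassified = False
        for _, label in self.ranks:
            if seen_unclassified and label != "unclassified":
                raise ValueError(
                    "classified rank below an unclassified one "
                    f"in {self.otu_id}")
            if label == "unclassified":
                seen_unclassified = True

    def label_at(self, rank_name: str) -> str | None:
        for name, label in self.ranks:
            if name == rank_name:
                return label
        return None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, label in self.ranks)


class ReferenceDatabase:
    """Reference 16S sequences with fixed-depth taxonomy paths."""

    def __init__(self, records, rank_names):
        """``records``: iterable of (seq_id, sequence, taxonomy path tuple)."""
        self.rank_names = tuple(rank_names)
        self.records = []
        seen = set()
        for seq_id, seq, path in records:
            if seq_id in seen:
                raise ValueError(f"duplicate reference id: {seq_id!r}")
            seen.add(seq_id)
            path = tuple(path)
            if len(path) != len(self.rank_names):
                raise ValueError(
                    f"taxonomy path depth {len(path)} != "
                    f"{len(self.rank_names)} for {seq_id!r}")
            self.records.append((str(seq_id), str(seq).upper(), path))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def seq_ids(self):
        return [r[0] for r in self.records]

    @property
    def sequences(self):
        return [r[1] for r in self.records]

    @property
    def taxonomies(self):
        return [r[2] for r in self.records]
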