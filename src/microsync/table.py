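"""OTU count tables, taxonomy maps and sample metadata.

The central container is :class:`OtuTable`, an integer count matrix with
samples as rows and OTUs as columns, wrapped around a pandas DataFrame.
Readers and writers speak the classic QIIME-style tab-separated dialect
(first column ``#OTU ID``, one column per sample, optional trailing
``taxonomy`` column with a semicolon-separated Greengenes-style lineage).

Table-level preprocessing lives here as well: the low-abundance filter
(OTUs kept only if their grand-total count exceeds a fixed fraction of all
reads), lineage-based exclusion (e.g. the Chloroplast class, which in the
Greengenes taxonomy collects eukaryotic plastid reads), rarefaction to a
common sequencing depth, and aggregation of OTUs to a higher taxonomic
rank such as genus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CALENDAR_MONTHS",
    "STUDY_MONTHS",
    "STAGES",
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "filter_low_abundance",
    "remove_lineage",
    "rarefy",
    "aggregate_by_rank",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = {r: r[0] if r != "kingdom" else "k" for r in RANKS}
# Greengenes single-letter prefixes: k__, p__, c__, o__, f__, g__, s__

CALENDAR_MONTHS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: The nine sampling months of the survey design (9 sites x 9 months).
STUDY_MONTHS = ("Jan", "Mar", "Apr", "May", "Jun", "Aug", "Sep", "Oct", "Dec")

#: Seasonal stages obtained from UPGMA of community distances.
STAGES: dict[str, tuple[str, ...]] = {
    "Dec-Jan": ("Dec", "Jan"),
    "Mar-Apr": ("Mar", "Apr"),
    "May-Jun": ("May", "Jun"),
    "Aug-Oct": ("Aug", "Sep", "Oct"),
}


def month_sort_key(month: str) -> int:
    return CALENDAR_MONTHS.index(month)


def stage_of_month(month: str) -> str | None:
    for stage, months in STAGES.items():
        if month in months:
            return stage
    return None


class OtuTableError(ValueError):
    pass


class OtuTable:
    """Integer count matrix, rows = samples, columns = OTUs.

    Row and column order is preserved exactly as given; identifiers must be
    unique and counts non-negative integers.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise OtuTableError("duplicate sample ids")
        if data.columns.has_duplicates:
            raise OtuTableError("duplicate OTU ids")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise OtuTableError("counts must be integers")
            data = data.astype(np.int64)
        if values.size and (data.to_numpy() < 0).any():
            raise OtuTableError("counts must be non-negative")
        self.data = data.astype(np.int64, copy=False)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.data.to_numpy().sum())

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise OtuTableError(f"unknown sample ids: {missing}")
        return OtuTable(self.data.loc[list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.data[list(otu_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} samples x {m} OTUs)"


class TaxonomyMap:
    """Mapping OTU id -> lineage (one name per rank, '' = unassigned)."""

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for otu, names in lineages.items():
            names = tuple(names)
            if len(names) > len(RANKS):
                raise OtuTableError(f"lineage of {otu} has more than {len(RANKS)} ranks")
            names = names + ("",) * (len(RANKS) - len(names))
            self._lineages[otu] = names

    @classmethod
    def from_strings(cls, strings: Mapping[str, str]) -> "TaxonomyMap":
        """Parse 'k__Bacteria; p__Actinobacteria; ...' lineage strings."""
        out = {}
        for otu, s in strings.items():
            names = []
            for part in str(s).split(";"):
                part = part.strip()
                if len(part) >= 3 and part[1:3] == "__":
                    part = part[3:]
                names.append(part.strip())
            out[otu] = names
        return cls(out)

    def __contains__(self, otu: str) -> bool:
        return otu in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def otus(self) -> list[str]:
        return list(self._lineages)

    def lineage(self, otu: str) -> tuple[str, ...]:
        return self._lineages[otu]

    def name_at(self, otu: str, rank: str) -> str:
        if rank not in RANKS:
            raise OtuTableError(f"unknown rank {rank!r}")
        return self._lineages[otu][RANKS.index(rank)]

    def label_at(self, otu: str, rank: str) -> str:
        """Aggregation label at ``rank``.

        Assigned OTUs label as their name at the rank. OTUs unassigned at
        the rank fall back to ``unclassified <most specific assigned name>``
        so that, e.g., unclassified genera of two different families remain
        distinct aggregate taxa.
        """
        if rank not in RANKS:
            raise OtuTableError(f"unknown rank {rank!r}")
        idx = RANKS.index(rank)
        names = self._lineages[otu]
        if names[idx]:
            return names[idx]
        for j in range(idx - 1, -1, -1):
            if names[j]:
                return f"unclassified {names[j]}"
        return "unclassified"

    def to_string(self, otu: str) -> str:
        names = self._lineages[otu]
        return "; ".join(f"{_RANK_PREFIX[r]}__{n}" for r, n in zip(RANKS, names))

    def to_series(self) -> pd.Series:
        return pd.Series({o: self.to_string(o) for o in self._lineages}, name="taxonomy")


@dataclass
class SampleMetadata:
    """Per-sample site, month, and (optionally) seasonal stage."""

    records: dict[str, dict[str, str | None]] = field(default_factory=dict)

    @classmethod
    def from_sample_ids(cls, sample_ids: Iterable[str]) -> "SampleMetadata":
        """Derive metadata from 'Month.Site' sample ids (e.g. 'Apr.MS')."""
        records = {}
        for sid in sample_ids:
            month, _, site = sid.partition(".")
            if month not in CALENDAR_MONTHS or not site:
                raise OtuTableError(f"sample id {sid!r} is not of the form Month.Site")
            records[sid] = {"site": site, "month": month, "stage": stage_of_month(month)}
        return cls(records)

    def __contains__(self, sid: str) -> bool:
        return sid in self.records

    def site(self, sid: str) -> str:
        return self.records[sid]["site"]

    def month(self, sid: str) -> str:
        return self.records[sid]["month"]

    def stage(self, sid: str) -> str | None:
        return self.records[sid].get("stage")

    def set_stage(self, sid: str, stage: str | None) -> None:
        if stage is not None and stage not in STAGES and not stage.startswith("group"):
            raise OtuTableError(f"unknown stage label {stage!r}")
        self.records[sid]["stage"] = stage

    def samples_by_month(self, sample_ids: Sequence[str] | None = None) -> dict[str, list[str]]:
        sids = sample_ids if sample_ids is not None else list(self.records)
        out: dict[str, list[str]] = {}
        for sid in sids:
            out.setdefault(self.month(sid), []).append(sid)
        return dict(sorted(out.items(), key=lambda kv: month_sort_key(kv[0])))

    def samples_by_stage(self, sample_ids: Sequence[str] | None = None) -> dict[str, list[str]]:
        sids = sample_ids if sample_ids is not None else list(self.records)
        out: dict[str, list[str]] = {}
        for sid in sids:
            st = self.stage(sid)
            if st is not None:
                out.setdefault(st, []).append(sid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": sid, "site": r["site"], "month": r["month"],
                 "stage": r.get("stage") or ""}
                for sid, r in self.records.items()
            ]
        ).set_index("sample_id")

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = {}
        for _, row in df.iterrows():
            records[row["sample_id"]] = {
                "site": row["site"],
                "month": row["month"],
                "stage": row["stage"] or None,
            }
        return cls(records)


# -- I/O ----------------------------------------------------------------


def read_otu_table(path: str | Path) -> tuple[OtuTable, TaxonomyMap | None]:
    """Read a QIIME-style TSV OTU table (OTUs as rows, samples as columns).

    The first column holds OTU ids (header ``#OTU ID`` or anything else);
    a trailing ``taxonomy`` column, if present, is parsed into a
    :class:`TaxonomyMap`. Cells must be integers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df = df.set_index(df.columns[0])
    tax = None
    if df.columns.size and df.columns[-1].lower() == "taxonomy":
        tax = TaxonomyMap.from_strings(df[df.columns[-1]].to_dict())
        df = df.drop(columns=df.columns[-1])
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise OtuTableError(f"duplicate OTU ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise OtuTableError(f"duplicate sample ids: {dupes}")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            try:
                counts[i, j] = int(val)
            except (TypeError, ValueError):
                raise OtuTableError(
                    f"non-integer count {val!r} at (OTU {df.index[i]!r}, sample {col!r})"
                ) from None
    table = OtuTable(pd.DataFrame(counts.T, index=list(df.columns), columns=list(df.index)))
    return table, tax


def write_otu_table(table: OtuTable, path: str | Path, tax: TaxonomyMap | None = None) -> None:
    """Write an OTU table in the same dialect ``read_otu_table`` accepts."""
    df = table.data.T.copy()
    df.index.name = "#OTU ID"
    if tax is not None:
        df["taxonomy"] = [tax.to_string(o) if o in tax else "" for o in df.index]
    df.to_csv(path, sep="\t")


# -- table-level filters ------------------------------------------------


def filter_low_abundance(table: OtuTable, min_fraction: float = 1e-5) -> OtuTable:
    """Keep OTUs whose total count is strictly greater than
    ``min_fraction`` of the grand total over all samples.

    The default 1e-5 is the 0.001%-of-total-reads rule.
    """
    if not (0 <= min_fraction < 1):
        raise OtuTableError("min_fraction must be in [0, 1)")
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise OtuTableError("empty table")
    totals = table.otu_totals()
    threshold = min_fraction * table.grand_total()
    keep = totals[totals > threshold].index
    return table.select_otus(list(keep))


def remove_lineage(table: OtuTable, tax: TaxonomyMap, rank: str, name: str) -> OtuTable:
    """Drop every OTU whose lineage carries ``name`` at ``rank``.

    Matching is exact on the stored name (prefix-stripped), so
    ``remove_lineage(t, tax, "class", "Chloroplast")`` drops plastid OTUs.
    """
    keep = [
        o for o in table.otu_ids
        if o not in tax or tax.name_at(o, rank) != name
    ]
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample uniformly without replacement to ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning. Sampling is
    multivariate hypergeometric, reproducible for a fixed seed.
    """
    if depth < 1:
        raise OtuTableError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not kept:
        raise OtuTableError(f"no sample has >= {depth} reads")
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) shallower than {depth}: {dropped}",
            stacklevel=2,
        )
    rows = []
    for s in kept:
        counts = table.data.loc[s].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    return OtuTable(pd.DataFrame(np.array(rows), index=kept, columns=table.otu_ids))


def aggregate_by_rank(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU counts into taxa at ``rank`` (e.g. genus).

    OTUs unassigned at the rank aggregate under their most specific assigned
    prefix (see :meth:`TaxonomyMap.label_at`), so unclassified genera of
    different families remain distinct columns.
    """
    labels = {}
    for otu in table.otu_ids:
        if otu not in tax:
            labels[otu] = "unclassified"
        else:
            labels[otu] = tax.label_at(otu, rank)
    grouped = table.data.T.groupby(pd.Series(labels), sort=False).sum().T
    return OtuTable(grouped)
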