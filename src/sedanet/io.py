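"""Core data containers and tabular/graph I/O.

The pipeline's central object is a :class:`CountMatrix`: a time-ordered
sample-by-family table of sequence read counts with a calibrated age per
sample (kyr BP, increasing = older).  Families are annotated with habitat
(pelagic/benthic) and functional group via :class:`TaxonAnnotation`, and
environmental proxies (IP25, SST) travel as :class:`ProxySeries` on their
own age grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

HABITATS = ("pelagic", "benthic", "excluded")
TROPHIC = ("phototrophic", "heterotrophic", "mixotrophic", "na")


class InputError(ValueError):
    """Raised when an input file or object violates the format contract."""


@dataclass
class CountMatrix:
    """Samples x families integer count table with per-sample ages.

    ``counts`` is indexed by sample id (rows, stratigraphic order) with one
    column per family.  ``ages`` is indexed identically, in kyr BP, and must
    be strictly increasing down-core.
    """

    counts: pd.DataFrame
    ages: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.ages = pd.Series(np.asarray(self.ages, dtype=float),
                              index=self.counts.index, name="age")
        if self.counts.index.has_duplicates:
            raise InputError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise InputError("duplicate family names")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise InputError("counts must be integers")
                self.counts = self.counts.round().astype(np.int64)
                vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise InputError("counts must be non-negative")
        if len(self.ages) > 1 and not (np.diff(self.ages.to_numpy()) > 0).all():
            raise InputError("ages must be strictly increasing down-core")

    # -- convenience -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_families(self, families: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(families)], self.ages)


@dataclass
class TaxonAnnotation:
    """Per-family habitat / functional group / trophic mode labels."""

    table: pd.DataFrame  # index: family; columns: habitat, functional_group, trophic

    def __post_init__(self) -> None:
        t = self.table
        missing = {"habitat", "functional_group", "trophic"} - set(t.columns)
        if missing:
            raise InputError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise InputError("annotation has duplicate families")
        bad = set(t["habitat"]) - set(HABITATS)
        if bad:
            raise InputError(f"unknown habitat labels: {sorted(bad)}")
        bad = set(t["trophic"]) - set(TROPHIC)
        if bad:
            raise InputError(f"unknown trophic labels: {sorted(bad)}")

    def habitat_of(self, family: str) -> str:
        return str(self.table.loc[family, "habitat"])

    def group_of(self, family: str) -> str:
        return str(self.table.loc[family, "functional_group"])

    def families_in_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.index[t["functional_group"] == group])


@dataclass
class ProxySeries:
    """Age-value pairs for one paleo-environmental proxy (own age grid)."""

    ages: np.ndarray
    values: np.ndarray
    name: str = "proxy"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.values.shape:
            raise InputError("proxy ages and values must be 1-D and equal length")
        if len(self.ages) < 2:
            raise InputError("proxy series needs at least 2 points")
        if len(np.unique(self.ages)) != len(self.ages):
            raise InputError("duplicate proxy ages")
        if not np.isfinite(self.values).all() or not np.isfinite(self.ages).all():
            raise InputError("proxy ages/values must be finite")
        order = np.argsort(self.ages)
        self.ages = self.ages[order]
        self.values = self.values[order]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, age_column: str = "age") -> CountMatrix:
    """Read a TSV count table (rows = samples, columns = families).

    The first column is taken as the sample id; ``age_column`` holds the
    calibrated age in kyr BP.  Samples are sorted by age ascending.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if age_column not in df.columns:
        raise InputError(f"missing age column {age_column!r}")
    if df.index.has_duplicates:
        raise InputError("duplicate sample ids")
    ages = df[age_column].astype(float)
    counts = df.drop(columns=[age_column])
    counts.index.name = None
    counts.columns.name = None
    order = np.argsort(ages.to_numpy(), kind="stable")
    return CountMatrix(counts.iloc[order], ages.iloc[order])


def write_count_table(cm: CountMatrix, path: str | Path,
                      age_column: str = "age") -> None:
    out = cm.counts.copy()
    out.insert(0, age_column, cm.ages)
    out.to_csv(path, sep="\t", index_label="sample")


def read_annotation(path: str | Path) -> TaxonAnnotation:
    return TaxonAnnotation(pd.read_csv(path, sep="\t", index_col=0))


def write_annotation(ann: TaxonAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="family")


def read_proxy_csv(path: str | Path, name: str | None = None) -> ProxySeries:
    df = pd.read_csv(path)
    if not {"age", "value"} <= set(df.columns):
        raise InputError("proxy CSV needs columns age,value")
    return ProxySeries(df["age"].to_numpy(), df["value"].to_numpy(),
                       name=name or Path(path).stem)


def write_proxy_csv(proxy: ProxySeries, path: str | Path) -> None:
    pd.DataFrame({"age": proxy.ages, "value": proxy.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Kraken2 reports
# ---------------------------------------------------------------------------

def _parse_one_report(path: str | Path, clade_counts: bool) -> dict[str, int]:
    """Family-level (rank code F) counts from a standard 6-column report."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise InputError(f"{path}: malformed line {lineno}")
            try:
                clade = int(parts[1])
                direct = int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}: malformed line {lineno}") from exc
            rank = parts[3].strip()
            name = parts[5].strip()
            if rank == "F":
                out[name] = out.get(name, 0) + (clade if clade_counts else direct)
    if not out:
        warnings.warn(f"{path}: no rank-F rows; sample will be all zeros")
    return out


def parse_kraken2_reports(paths: Sequence[str | Path],
                          merged_and_paired: bool = False,
                          clade_counts: bool = True) -> CountMatrix:
    """Assemble a CountMatrix from Kraken2 report files.

    With ``merged_and_paired`` the path list must have even length and
    consecutive pairs (merged reads, unmerged paired reads of the same
    sample) are summed.  Counts default to clade-level reads at rank F.
    Ages are placeholders (0, 1, ...) in file order; set real ages before
    stratigraphic analysis.
    """
    if merged_and_paired:
        if len(paths) % 2:
            raise InputError("merged_and_paired requires an even number of reports")
        groups = [(paths[i], paths[i + 1]) for i in range(0, len(paths), 2)]
    else:
        groups = [(p,) for p in paths]
    rows = []
    names = []
    for grp in groups:
        tally: dict[str, int] = {}
        for p in grp:
            for fam, n in _parse_one_report(p, clade_counts).items():
                tally[fam] = tally.get(fam, 0) + n
        rows.append(tally)
        names.append(Path(grp[0]).stem)
    families = sorted({f for r in rows for f in r})
    counts = pd.DataFrame(
        [[r.get(f, 0) for f in families] for r in rows],
        index=names, columns=families, dtype=np.int64)
    ages = pd.Series(np.arange(len(rows), dtype=float), index=names)
    return CountMatrix(counts, ages)


# ---------------------------------------------------------------------------
# habitat split
# ---------------------------------------------------------------------------

def split_by_habitat(cm: CountMatrix, ann: TaxonAnnotation
                     ) -> tuple[CountMatrix, CountMatrix]:
    """Partition families into pelagic and benthic matrices.

    Families annotated ``excluded`` are dropped (taxonomic curation is
    expressed entirely through the annotation table).  Column order within
    each partition follows the input.
    """
    unknown = [f for f in cm.families if f not in ann.table.index]
    if unknown:
        raise InputError(f"unannotated families: {unknown}")
    pel = [f for f in cm.families if ann.habitat_of(f) == "pelagic"]
    ben = [f for f in cm.families if ann.habitat_of(f) == "benthic"]
    return cm.select_families(pel), cm.select_families(ben)


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML or an edge-list TSV (source, target, weight)."""
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(net, str(path))
    elif fmt in ("tsv", "edgelist"):
        rows = [{"source": u, "target": v, "weight": d.get("weight", 1.0)}
                for u, v, d in net.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise InputError(f"unknown network format {format!r}")


def import_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    fmt = format.lower()
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt in ("tsv", "edgelist"):
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return g
    raise InputError(f"unknown network format {format!r}")
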