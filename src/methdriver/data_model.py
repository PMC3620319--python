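"""Domain containers and readers/writers for the tabular formats of the pipeline.

Matrices (methylation beta values, normalized expression, detection
p-values, ternary alteration states) live in :class:`pandas.DataFrame`
objects with features on the rows and samples on the columns. Gene sets
are plain ``dict[str, frozenset[str]]`` collections; the protein
interaction network is a :class:`networkx.Graph`. Identifiers are opaque
strings throughout — probe/gene mapping is supplied by the locus
annotation table, never computed here.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed vocabulary for the chromosome column of a locus annotation
CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])
SEX_CHROMOSOMES = frozenset({"X", "Y"})

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"


class FormatError(ValueError):
    """A file does not follow its declared format."""


class ValidationError(ValueError):
    """Structurally valid input violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path, orientation: str = "features_by_samples") -> pd.DataFrame:
    """Read a TSV matrix (header = sample ids, first column = feature ids).

    ``orientation`` declares how the file is laid out; ``samples_by_features``
    files are transposed on read so the in-memory convention is always
    features x samples.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        out = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"malformed numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if orientation == "samples_by_features":
        out = out.T
    return out


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV.

    Values are printed with up to 10 significant digits, which round-trips
    bit-exactly through :func:`read_matrix` for decimal text of that
    precision.
    """
    df.to_csv(path, sep="\t", float_format="%.10g")


def validate_beta_matrix(df: pd.DataFrame) -> None:
    """Check the beta-matrix invariants: complete, finite, values in [0, 1)."""
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("beta matrix contains missing values")
    if (vals < 0).any() or (vals >= 1).any():
        raise ValidationError("beta values must lie in [0, 1)")


# ---------------------------------------------------------------------------
# gene sets (GMT), gene lists


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")


def read_gene_list(path) -> frozenset[str]:
    """Read a one-gene-per-line text file (blank lines ignored)."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# interaction network


def read_edge_list(path) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected, simple graph.

    Edges are deduplicated regardless of orientation; self-loops are
    dropped with a logged count.
    """
    graph = nx.Graph()
    self_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            a, b = fields
            if a == b:
                self_loops += 1
                continue
            graph.add_edge(a, b)
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def neighbors_of_set(graph: nx.Graph, seeds: Iterable[str]) -> frozenset[str]:
    """Union of direct neighbors of the seed genes, minus the seeds themselves.

    Seeds absent from the network contribute nothing.
    """
    seeds = frozenset(seeds)
    out: set[str] = set()
    for s in seeds:
        if s in graph:
            out.update(graph.neighbors(s))
    return frozenset(out - seeds)


# ---------------------------------------------------------------------------
# sample sheet and locus annotation


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet: columns sample_id, group, optional subtype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet must have columns {sorted(required)}")
    df = df.copy()
    if "subtype" not in df.columns:
        df["subtype"] = pd.NA
    df["subtype"] = df["subtype"].replace({"": pd.NA})
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    bad = set(df["group"]) - {GROUP_TUMOR, GROUP_NORMAL}
    if bad:
        raise ValidationError(f"unknown sample group labels: {sorted(bad)}")
    labeled_normals = df.loc[
        (df["group"] == GROUP_NORMAL) & df["subtype"].notna(), "sample_id"
    ]
    if len(labeled_normals):
        raise ValidationError(
            f"subtype labels are defined for tumors only: {labeled_normals.tolist()[:5]}"
        )
    return df


def tumor_samples(sheet: pd.DataFrame) -> list[str]:
    return sheet.loc[sheet["group"] == GROUP_TUMOR, "sample_id"].tolist()


def normal_samples(sheet: pd.DataFrame) -> list[str]:
    return sheet.loc[sheet["group"] == GROUP_NORMAL, "sample_id"].tolist()


def read_annotation(path) -> pd.DataFrame:
    """Read the locus annotation table: columns locus_id, gene_id, chromosome."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "gene_id", "chromosome"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation must have columns {sorted(required)}")
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["locus_id"].duplicated().any():
        raise ValidationError("each locus must map to exactly one gene")
    bad = set(df["chromosome"]) - CHROMOSOMES
    if bad:
        raise ValidationError(f"chromosome labels outside closed vocabulary: {sorted(bad)}")
    return df.set_index("locus_id") if df.index.name != "locus_id" else df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)
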