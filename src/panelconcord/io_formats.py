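"""Tabular input/output for the concordance pipeline.

Everything on disk is plain tab-separated text. Expression matrices carry a
``# scale=`` comment line distinguishing raw positive intensities from log2
values; manifests, sample metadata and interaction edge lists are ordinary
TSV tables with a header row. Readers validate and reject malformed input
rather than silently coercing it, and every writer/reader pair round-trips
valid data (floats are serialized with 12 significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError

SCALE_INTENSITY = "intensity"
SCALE_LOG2 = "log2"

MANIFEST_COLUMNS = [
    "probe_id",
    "panel_id",
    "gene_symbol",
    "aliases",
    "refseq_ids",
    "entrez_id",
    "sequence",
    "transcript_position",
]

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "her2_ihc",
    "group",
    "replicate_kind",
    "extract",
    "order_index",
]

EDGE_COLUMNS = ["source", "target", "effect", "mechanism"]

#: IHC scores that define the HER2-positive group (2+/3+ staining).
HER2_POSITIVE_IHC = frozenset({"2+", "3+"})


@dataclass
class ExpressionMatrix:
    """A probes x samples matrix for one panel.

    ``values`` is a DataFrame indexed by probe (or gene) id with one column
    per sample. ``scale`` is either ``"intensity"`` (strictly positive raw
    values) or ``"log2"``.
    """

    panel_id: str
    values: pd.DataFrame
    scale: str = SCALE_INTENSITY

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_INTENSITY, SCALE_LOG2):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.scale == SCALE_INTENSITY and arr.size and (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise FormatError(
                "nonpositive intensity at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(self.panel_id, values, scale or self.scale)


def read_expression_matrix(path, scale: str | None = None, panel_id: str | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The first column holds probe ids, remaining columns one sample each.
    Leading ``#`` comment lines are honoured; a ``# scale=`` line declares
    the value scale and an explicit ``scale`` argument overrides it.
    """
    header_scale = None
    file_panel = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("scale="):
                header_scale = body.split("=", 1)[1].strip()
            elif body.startswith("panel="):
                file_panel = body.split("=", 1)[1].strip()
    resolved = scale or header_scale
    if resolved is None:
        raise FormatError(f"{path}: no scale declared and no scale hint given")
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from None
    return ExpressionMatrix(panel_id or file_panel or "", numeric, resolved)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write ``matrix`` as TSV with ``# scale=``/``# panel=`` comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        if matrix.panel_id:
            fh.write(f"# panel={matrix.panel_id}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.12g")


def read_probe_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV and validate its invariants."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    df["transcript_position"] = pd.to_numeric(df["transcript_position"], errors="raise").astype(int)
    df["entrez_id"] = df["entrez_id"].replace("", pd.NA)
    validate_probe_manifest(df)
    return df


def validate_probe_manifest(df: pd.DataFrame) -> None:
    for panel, grp in df.groupby("panel_id"):
        if grp["probe_id"].duplicated().any():
            dup = grp["probe_id"][grp["probe_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate probe id {dup!r} within panel {panel!r}")
    bad = df["sequence"].str.fullmatch(r"[ACGT]+").fillna(False)
    if not bad.all():
        pid = df.loc[~bad, "probe_id"].iloc[0]
        raise FormatError(f"probe {pid!r}: sequence empty or not over {{A,C,G,T}}")
    if (df["transcript_position"] < 1).any():
        pid = df.loc[df["transcript_position"] < 1, "probe_id"].iloc[0]
        raise FormatError(f"probe {pid!r}: transcript_position must be >= 1")


def write_probe_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    df["order_index"] = pd.to_numeric(df["order_index"], errors="raise").astype(int)
    df["extract"] = pd.to_numeric(df["extract"], errors="raise").astype(int)
    validate_sample_metadata(df)
    return df


def validate_sample_metadata(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    expected = df["her2_ihc"].isin(HER2_POSITIVE_IHC).map({True: "HER2+", False: "HER2-"})
    mism = df["group"] != expected
    if mism.any():
        sid = df.loc[mism, "sample_id"].iloc[0]
        raise FormatError(f"sample {sid!r}: group inconsistent with her2_ihc")
    for subj, grp in df.groupby("subject_id"):
        if grp["order_index"].duplicated().any():
            raise FormatError(f"subject {subj!r}: order_index not unique")


def write_sample_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def read_interaction_edges(path) -> nx.DiGraph:
    """Read a directed curated-interaction edge list.

    Parallel edges collapse to a simple directed graph keeping the
    attributes of the first-seen edge; self-loops are dropped on load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: edge list missing columns {missing}")
    graph = nx.DiGraph()
    for row in df.itertuples(index=False):
        if row.source == row.target:
            continue
        if graph.has_edge(row.source, row.target):
            continue
        graph.add_edge(row.source, row.target, effect=row.effect, mechanism=row.mechanism)
    return graph


def write_interaction_edges(graph: nx.DiGraph, path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "effect": d.get("effect", "unspecified"),
            "mechanism": d.get("mechanism", ""),
        }
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
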