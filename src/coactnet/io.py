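"""Readers and writers for the study's tabular layouts, networks and reports.

Expression tables are accepted in long form (subject, group, region, value)
or wide form (subject, group, one column per region), in CSV or XLSX;
layout and header synonyms are auto-detected. All CSVs are UTF-8, comma
delimited, "." decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BehaviorTable, ExpressionMatrix, RegionCatalogue
from .network import ThresholdedNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_behavior",
    "write_behavior",
    "write_network",
    "read_network",
    "write_report",
    "read_catalogue",
]

_SUBJECT_SYNONYMS = {"subject", "subject_id", "id", "animal", "rat"}
_GROUP_SYNONYMS = {"group", "condition", "treatment"}
_REGION_SYNONYMS = {"region", "brain_region", "area", "abbreviation"}
_VALUE_SYNONYMS = {"value", "density", "nuclei_density", "pcreb", "expression"}
_FREEZING_SYNONYMS = {
    "freezing",
    "freezing_s",
    "freezing_time",
    "total_freezing_time",
    "total_freezing_time_s",
    "freezing_time_s",
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _normalize(name: str) -> str:
    return str(name).strip().casefold().replace(" ", "_").replace("(", "").replace(
        ")", ""
    )


def _find_column(df: pd.DataFrame, synonyms: set[str]) -> str | None:
    for col in df.columns:
        if _normalize(col) in synonyms:
            return col
    return None


def read_catalogue(path: str | Path) -> RegionCatalogue:
    """Read a region catalogue (abbreviation, full_name, system, flag) table."""
    return RegionCatalogue.from_frame(_read_table(path))


def read_expression(
    path: str | Path, region_catalogue: RegionCatalogue
) -> ExpressionMatrix:
    """Read an expression table, auto-detecting long or wide layout.

    Region names are matched case-insensitively against the catalogue.
    Unknown regions, duplicate (subject, region) cells and missing cells
    are rejected (no imputation).
    """
    df = _read_table(path)
    if len(df) == 0:
        raise ValueError("no rows")
    subject_col = _find_column(df, _SUBJECT_SYNONYMS)
    group_col = _find_column(df, _GROUP_SYNONYMS)
    if subject_col is None or group_col is None:
        raise ValueError("expression table needs subject and group columns")
    region_col = _find_column(df, _REGION_SYNONYMS)
    value_col = _find_column(df, _VALUE_SYNONYMS)

    if region_col is not None and value_col is not None:  # long layout
        regions = [
            region_catalogue.lookup(name).abbreviation
            for name in df[region_col].astype(str)
        ]
        long = pd.DataFrame(
            {
                "subject": df[subject_col].astype(str),
                "group": df[group_col].astype(str),
                "region": regions,
                "value": pd.to_numeric(df[value_col], errors="raise"),
            }
        )
        dup = long.duplicated(subset=["subject", "region"])
        if dup.any():
            pairs = long.loc[dup, ["subject", "region"]].to_records(index=False)
            raise ValueError(f"duplicate (subject, region) cells: {list(pairs)[:5]}")
        wide = long.pivot(index="subject", columns="region", values="value")
        # preserve catalogue ordering for the regions present
        wide = wide[[r for r in region_catalogue.abbreviations if r in wide.columns]]
        groups = long.drop_duplicates("subject").set_index("subject")["group"]
        groups = groups.reindex(wide.index)
        return ExpressionMatrix(wide, groups, region_catalogue)

    # wide layout: remaining columns must all be catalogue regions
    region_cols = [c for c in df.columns if c not in (subject_col, group_col)]
    if not region_cols:
        raise ValueError("no region columns found")
    renamed = {c: region_catalogue.lookup(str(c)).abbreviation for c in region_cols}
    data = df.set_index(df[subject_col].astype(str))[region_cols].rename(
        columns=renamed
    )
    data = data.apply(pd.to_numeric, errors="raise")
    groups = pd.Series(
        df[group_col].astype(str).to_numpy(), index=data.index, name="group"
    )
    return ExpressionMatrix(data, groups, region_catalogue)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix in long layout (subject, group, region, value)."""
    path = Path(path)
    long = (
        expr.data.reset_index(names="subject")
        .melt(id_vars="subject", var_name="region", value_name="value")
        .merge(
            expr.groups.rename("group").rename_axis("subject").reset_index(),
            on="subject",
        )[["subject", "group", "region", "value"]]
        .sort_values(["subject", "region"], kind="stable")
    )
    long.to_csv(path, index=False)
    return path


def read_behavior(path: str | Path) -> BehaviorTable:
    """Read a behavior table (subject, group, total freezing time)."""
    df = _read_table(path)
    if len(df) == 0:
        raise ValueError("no rows")
    subject_col = _find_column(df, _SUBJECT_SYNONYMS)
    group_col = _find_column(df, _GROUP_SYNONYMS)
    freezing_col = _find_column(df, _FREEZING_SYNONYMS)
    if subject_col is None or group_col is None or freezing_col is None:
        raise ValueError(
            "behavior table needs subject, group and freezing-time columns"
        )
    freezing = pd.to_numeric(df[freezing_col], errors="coerce")
    if freezing.isna().any():
        raise ValueError("non-numeric freezing values")
    return BehaviorTable(
        pd.DataFrame(
            {
                "subject": df[subject_col].astype(str),
                "group": df[group_col].astype(str),
                "freezing_s": freezing.astype(float),
            }
        )
    )


def write_behavior(table: BehaviorTable, path: str | Path) -> Path:
    path = Path(path)
    table.df[["subject", "group", "freezing_s"]].to_csv(path, index=False)
    return path


def write_network(
    net: ThresholdedNetwork, path: str | Path, format: str = "edgelist"
) -> Path:
    """Write a thresholded network as a CSV edge list or GraphML.

    The edge list has columns (region_a, region_b, weight, signed_r); GraphML
    carries the node set (with anatomical system attributes when the network
    was built from a catalogued matrix) and all edge attributes, so isolates
    round-trip too.
    """
    path = Path(path)
    if format == "edgelist":
        net.edge_list().to_csv(path, index=False)
        return path
    if format == "graphml":
        import networkx as nx

        g = net.to_networkx()
        g.graph["level"] = float(net.level)
        g.graph["n"] = int(net.n)
        nx.write_graphml(g, path)
        return path
    raise ValueError(f"unknown format: {format!r}")


def read_network(path: str | Path) -> ThresholdedNetwork:
    """Read a GraphML file written by :func:`write_network` back into a network."""
    import networkx as nx

    g = nx.read_graphml(Path(path))
    nodes = list(g.nodes)
    n_nodes = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    weight = np.zeros((n_nodes, n_nodes))
    signed = np.zeros((n_nodes, n_nodes))
    for u, v, attrs in g.edges(data=True):
        i, j = index[u], index[v]
        weight[i, j] = weight[j, i] = float(attrs["weight"])
        signed[i, j] = signed[j, i] = float(attrs.get("signed_r", attrs["weight"]))
    return ThresholdedNetwork(
        level=float(g.graph.get("level", np.nan)),
        weight=pd.DataFrame(weight, index=nodes, columns=nodes),
        signed_r=pd.DataFrame(signed, index=nodes, columns=nodes),
        n=int(g.graph.get("n", 0)),
    )


def write_report(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Serialize named result tables, one CSV each, with stable column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False)
        paths[name] = target
    return paths
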