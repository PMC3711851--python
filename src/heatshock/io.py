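"""Plain-TSV readers and writers for every pipeline artefact.

All files are tab-separated UTF-8 with '.' decimals. Not-evaluated SLR
values are encoded as '-'; below-noise status travels in its own flag
columns, never as a suffix on the signal value.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from .chip import ChipSignalSet, PromoterMap
from .enrich import TermAnnotation

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_chip_signals",
    "write_chip_signals",
    "read_promoter_map",
    "write_promoter_map",
    "read_annotation",
    "write_annotation",
    "write_manifest",
    "file_sha256",
]


class FormatError(ValueError):
    """Malformed input file; the message carries row/column context."""


# ---------------------------------------------------------------------------
# expression matrix + design


def read_expression(matrix_path, design_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples log2 matrix and its design sheet.

    The matrix header must match the design's sample ids exactly (as a
    set); duplicate gene ids and non-numeric cells are format errors.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "cell_type", "condition", "replicate"}
    missing_cols = required - set(design.columns)
    if missing_cols:
        raise FormatError(f"design sheet lacks columns {sorted(missing_cols)}")
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"duplicated gene id {dup!r} in matrix")
    header = set(matrix.columns)
    design_ids = set(design["sample_id"])
    if header != design_ids:
        raise FormatError(
            f"matrix header and design sample ids differ: "
            f"only-in-matrix={sorted(header - design_ids)[:3]}, "
            f"only-in-design={sorted(design_ids - header)[:3]}"
        )
    non_numeric = matrix.columns[
        [not pd.api.types.is_numeric_dtype(matrix[c]) for c in matrix.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = matrix[pd.to_numeric(matrix[col], errors="coerce").isna()].index
        raise FormatError(
            f"non-numeric value in column {col!r}, gene {bad[0]!r}"
        )
    return matrix, design


def write_expression(matrix: pd.DataFrame, design: pd.DataFrame,
                     matrix_path, design_path) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ChIP signals + promoter map


def write_chip_signals(signals: ChipSignalSet, path) -> None:
    """Long form: probe_id, channel, replicate, intensity."""
    frames = []
    for channel, df in (("AB1", signals.ab1), ("AB0", signals.ab0)):
        long = df.reset_index().melt(
            id_vars="probe_id", var_name="column", value_name="intensity"
        )
        long["channel"] = channel
        long["replicate"] = long["column"].str.extract(r"_r(\d+)$").astype(int)
        frames.append(long[["probe_id", "channel", "replicate", "intensity"]])
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_chip_signals(path) -> ChipSignalSet:
    long = pd.read_csv(path, sep="\t")
    required = {"probe_id", "channel", "replicate", "intensity"}
    if missing := required - set(long.columns):
        raise FormatError(f"ChIP signal file lacks columns {sorted(missing)}")
    channels = {}
    for channel, sub in long.groupby("channel"):
        wide = sub.pivot(index="probe_id", columns="replicate", values="intensity")
        wide.columns = [f"{channel}_r{r}" for r in wide.columns]
        channels[channel] = wide
    if set(channels) != {"AB1", "AB0"}:
        raise FormatError(f"expected channels AB1 and AB0, got {sorted(channels)}")
    # restore file order of probes
    order = long["probe_id"].drop_duplicates().tolist()
    return ChipSignalSet(
        ab1=channels["AB1"].loc[order], ab0=channels["AB0"].loc[order]
    )


def write_promoter_map(pmap: PromoterMap, path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


def read_promoter_map(path) -> PromoterMap:
    """BED-like TSV: chrom, start, end, probe_id, promoter_id, strand
    (0-based half-open). Out-of-order probes within a promoter are sorted
    with a warning; start >= end or duplicate probes are format errors."""
    table = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "probe_id", "promoter_id", "strand"]
    if missing := set(required) - set(table.columns):
        raise FormatError(f"promoter map lacks columns {sorted(missing)}")
    if (table["start"] >= table["end"]).any():
        bad = table.loc[table["start"] >= table["end"]].iloc[0]
        raise FormatError(
            f"probe {bad['probe_id']!r}: start {bad['start']} >= end {bad['end']}"
        )
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe id {dup!r}")
    unsorted = (
        table.groupby("promoter_id", sort=False)["start"]
        .apply(lambda s: not s.is_monotonic_increasing)
        .any()
    )
    if unsorted:
        warnings.warn("probes out of genomic order within a promoter; sorting")
    return PromoterMap(table=table)


# ---------------------------------------------------------------------------
# annotation


def write_annotation(annotation: TermAnnotation, gene_term_path, dag_path) -> None:
    rows = [
        {"gene": g, "term": t}
        for t, genes in annotation.direct.items()
        for g in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
        gene_term_path, sep="\t", index=False
    )
    edges = [
        {"child": c, "parent": p}
        for c, ps in annotation.parents.items()
        for p in sorted(ps)
    ]
    pd.DataFrame(edges, columns=["child", "parent"]).to_csv(
        dag_path, sep="\t", index=False
    )


def read_annotation(gene_term_path, dag_path=None, universe=None) -> TermAnnotation:
    gt = pd.read_csv(gene_term_path, sep="\t")
    if missing := {"gene", "term"} - set(gt.columns):
        raise FormatError(f"gene-term file lacks columns {sorted(missing)}")
    direct: dict[str, set[str]] = {
        t: set(sub["gene"]) for t, sub in gt.groupby("term")
    }
    parents: dict[str, set[str]] = {}
    if dag_path is not None:
        dag = pd.read_csv(dag_path, sep="\t")
        if missing := {"child", "parent"} - set(dag.columns):
            raise FormatError(f"DAG file lacks columns {sorted(missing)}")
        for _, row in dag.iterrows():
            parents.setdefault(row["child"], set()).add(row["parent"])
            direct.setdefault(row["parent"], set())
    return TermAnnotation(
        direct=direct,
        parents=parents,
        universe=set(universe) if universe is not None else set(),
    )


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, seeds: dict, parameters: dict, inputs: dict) -> None:
    """Machine-readable record of a run: package version, every stage seed,
    parameters and input checksums."""
    from . import __version__

    manifest = {
        "package": "heatshock",
        "version": __version__,
        "seeds": seeds,
        "parameters": parameters,
        "input_checksums": {k: file_sha256(v) for k, v in inputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
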