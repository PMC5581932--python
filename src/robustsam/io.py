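"""CSV/TSV input and deterministic report output.

Expression matrices are plain CSV/TSV tables: one header row of sample
names, one gene-id column, genes in rows.  Group assignment comes either
from a sidecar two-column table (sample, group) or from sample names of the
form ``control_1``/``treatment_3`` in the header.  Missing values are
rejected outright (no imputation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    TREATMENT,
    SignificanceCall,
    StatisticResult,
    TruthLabels,
    TwoGroupExpression,
)

__all__ = [
    "read_expression",
    "read_group_file",
    "read_truth",
    "write_dataset",
    "write_truth",
    "write_statistics",
    "write_delta_table",
    "write_significant",
    "write_run_metadata",
]

FLOAT_FORMAT = "%.6g"


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_group_file(path: str | Path) -> dict[str, str]:
    """Sidecar table with columns (sample, group) -> mapping."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError("group file must have exactly two columns")
    if {str(v) for v in df.iloc[0]} & {"sample", "group"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_expression(
    path: str | Path, group_source: str | Path | dict[str, str] = "header"
) -> TwoGroupExpression:
    """Parse and validate a genes-x-samples CSV/TSV matrix.

    ``group_source`` is a sample->group mapping, a path to a sidecar
    two-column file, or the string ``"header"`` to derive groups from
    sample-name prefixes (text before the last underscore must be
    ``control`` or ``treatment``).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] < 4:
        raise ValueError("expected at least 4 sample columns")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene ids, e.g. {dupes!r}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell: {exc}") from exc

    samples = [str(c) for c in df.columns]
    if isinstance(group_source, (str, Path)) and group_source != "header":
        group_source = read_group_file(group_source)
    if group_source == "header":
        mapping = {s: s.rsplit("_", 1)[0] for s in samples}
    else:
        mapping = dict(group_source)
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ValueError(f"samples without group assignment: {missing!r}")
    group = np.array([mapping[s] for s in samples])
    bad = sorted(set(group) - {CONTROL, TREATMENT})
    if bad:
        raise ValueError(
            f"group labels must be 'control'/'treatment', got {bad!r}"
        )
    return TwoGroupExpression(
        values=values, gene_ids=df.index.to_numpy(str), group=group
    )


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")


def write_dataset(
    expr: TwoGroupExpression, path: str | Path, overwrite: bool = False
) -> Path:
    """Write the matrix as CSV with group-encoding sample names."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    counts: dict[str, int] = {}
    cols = []
    for g in expr.group:
        counts[g] = counts.get(g, 0) + 1
        cols.append(f"{g}_{counts[g]}")
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=cols)
    df.index.name = "gene_id"
    df.to_csv(path, float_format=FLOAT_FORMAT)
    return path


def write_truth(
    truth: TruthLabels,
    gene_ids: np.ndarray,
    path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Two-column TSV (gene_id, status in {up, down, null})."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    status = np.full(len(gene_ids), "null", dtype=object)
    status[truth.up_genes] = "up"
    status[truth.down_genes] = "down"
    pd.DataFrame({"gene_id": gene_ids, "status": status}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_truth(path: str | Path, gene_ids: np.ndarray) -> TruthLabels:
    """Read a truth TSV back into index-based labels (aligned to gene_ids)."""
    # keep_default_na: the literal status token "null" must survive parsing
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    status = df.set_index("gene_id")["status"]
    status = status.reindex(np.asarray(gene_ids, dtype=str))
    if status.isna().any():
        missing = status[status.isna()].index.tolist()[:5]
        raise ValueError(f"truth file misses gene ids, e.g. {missing!r}")
    arr = status.to_numpy()
    return TruthLabels(
        up_genes=np.flatnonzero(arr == "up"),
        down_genes=np.flatnonzero(arr == "down"),
    )


def write_statistics(
    result: StatisticResult, path: str | Path, overwrite: bool = False
) -> Path:
    """Per-gene statistic table as TSV, sorted by |statistic| descending
    within sign (positive side first)."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    df = result.to_frame()
    sign = np.sign(df["statistic"].to_numpy())
    df = (
        df.assign(_sign=-sign, _mag=-df["statistic"].abs())
        .sort_values(["_sign", "_mag"], kind="stable")
        .drop(columns=["_sign", "_mag"])
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_delta_table(
    table: pd.DataFrame, path: str | Path, overwrite: bool = False
) -> Path:
    path = Path(path)
    _check_overwrite(path, overwrite)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_significant(
    call: SignificanceCall,
    result: StatisticResult,
    path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Significant-gene list TSV (gene_id, statistic, direction).

    ``direction`` is the sign of the statistic: ``up`` = higher in control,
    ``down`` = higher in treatment.  An empty call writes a header-only
    table.
    """
    path = Path(path)
    _check_overwrite(path, overwrite)
    rows = []
    for idx in call.up_genes:
        rows.append((result.gene_ids[idx], result.statistic[idx], "up"))
    for idx in call.down_genes:
        rows.append((result.gene_ids[idx], result.statistic[idx], "down"))
    df = pd.DataFrame(rows, columns=["gene_id", "statistic", "direction"])
    if not df.empty:
        df = df.sort_values(
            "statistic", key=lambda s: -s.abs(), kind="stable"
        )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_run_metadata(
    path: str | Path, config: dict, overwrite: bool = True
) -> Path:
    """Echo the run configuration (flags, seed, package version) as JSON."""
    from . import __version__

    path = Path(path)
    _check_overwrite(path, overwrite)
    payload = {"robustsam_version": __version__, **config}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
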