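"""Readers and writers for trajectory inputs and alignment outputs.

A trajectory is a normalized (log-scale) gene-by-cell expression matrix plus a
per-cell pseudotime table. Expression is accepted either as a dense CSV (first
column gene ids, header row of cell ids) or as a CellRanger-style MatrixMarket
triple (matrix.mtx, genes.tsv, barcodes.tsv). Pseudotime is a two-column TSV
(cell_id, pseudotime).

Expression is assumed to be already normalized and log-transformed by an
upstream pipeline; nothing here renormalizes. All indices written to disk are
1-based; in memory everything is 0-based numpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("trajalign")


@dataclass
class TrajectoryData:
    """One condition: normalized expression and per-cell pseudotime.

    Attributes
    ----------
    name : str
        Label for the condition (used in logs and output tables).
    genes : list of str
        Gene identifiers, length ``g``, no duplicates.
    cells : list of str
        Cell identifiers, length ``c``.
    expression : ndarray of shape (g, c)
        Normalized log-scale expression, gene by cell.
    pseudotime : ndarray of shape (c,)
        Non-negative pseudotime per cell, ordered as ``cells``.
    """

    name: str
    genes: list = field(repr=False)
    cells: list = field(repr=False)
    expression: np.ndarray = field(repr=False)
    pseudotime: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        g, c = self.expression.shape
        if len(self.genes) != g or len(self.cells) != c:
            raise ValueError(
                f"expression is {g}x{c} but there are {len(self.genes)} genes "
                f"and {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        if self.pseudotime.shape != (c,) or not np.all(np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime must hold one finite value per cell")
        if self.pseudotime.min() < 0:
            raise ValueError("pseudotime values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _read_pseudotime(path: Path) -> pd.Series:
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower(): c for c in table.columns}
    if "cell_id" not in cols or "pseudotime" not in cols:
        raise ValueError(
            f"{path}: pseudotime table needs columns cell_id and pseudotime, "
            f"found {list(table.columns)}"
        )

    def parse(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    pt = table[cols["pseudotime"]].map(parse)
    if pt.isna().any():
        bad = table.loc[pt.isna(), cols["cell_id"]].head(5).tolist()
        raise ValueError(f"{path}: non-numeric pseudotime for cells {bad}")
    return pd.Series(pt.to_numpy(float), index=table[cols["cell_id"]].astype(str))


def read_trajectory(
    expression_path: str | Path,
    pseudotime_path: str | Path,
    format: str = "csv",
    name: str | None = None,
) -> TrajectoryData:
    """Read an expression matrix and its pseudotime table.

    Parameters
    ----------
    expression_path
        For ``format="csv"``: a dense CSV, first column gene ids, header row
        cell ids. For ``format="mtx"``: the ``matrix.mtx`` file; ``genes.tsv``
        and ``barcodes.tsv`` are looked up next to it.
    pseudotime_path
        TSV/CSV with columns ``cell_id`` and ``pseudotime``. The set of cell
        ids must equal the expression columns; rows are reordered to match.
    format
        ``"csv"`` or ``"mtx"``.
    """
    expression_path = Path(expression_path)
    pseudotime_path = Path(pseudotime_path)
    if format == "csv":
        frame = pd.read_csv(expression_path, index_col=0, float_precision="round_trip")
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
        matrix = frame.to_numpy(float)
    elif format == "mtx":
        matrix = scipy.io.mmread(expression_path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        matrix = np.asarray(matrix, dtype=float)
        folder = expression_path.parent
        genes_df = pd.read_csv(folder / "genes.tsv", sep="\t", header=None)
        barcodes_df = pd.read_csv(folder / "barcodes.tsv", sep="\t", header=None)
        genes = [str(g) for g in genes_df.iloc[:, 0]]
        cells = [str(c) for c in barcodes_df.iloc[:, 0]]
    else:
        raise ValueError(f"unknown expression format {format!r}")

    pt = _read_pseudotime(pseudotime_path)
    cell_set, pt_set = set(cells), set(pt.index)
    if cell_set != pt_set:
        missing = sorted(cell_set - pt_set)[:5]
        extra = sorted(pt_set - cell_set)[:5]
        raise ValueError(
            f"cell ids differ between expression and pseudotime; "
            f"missing from pseudotime: {missing}; unknown cells: {extra}"
        )
    return TrajectoryData(
        name=name or expression_path.stem,
        genes=genes,
        cells=cells,
        expression=matrix,
        pseudotime=pt.loc[cells].to_numpy(float),
    )


def _subset_genes(t: TrajectoryData, genes: Sequence[str]) -> TrajectoryData:
    index = {g: k for k, g in enumerate(t.genes)}
    rows = [index[g] for g in genes]
    return TrajectoryData(
        name=t.name,
        genes=list(genes),
        cells=list(t.cells),
        expression=t.expression[rows, :],
        pseudotime=t.pseudotime.copy(),
    )


def harmonize_genes(
    a: TrajectoryData,
    b: TrajectoryData,
    gene_list: Sequence[str] | None = None,
) -> tuple[TrajectoryData, TrajectoryData]:
    """Restrict both trajectories to a common gene set in a common order.

    The two trajectories must carry the same genes before any dissimilarity
    can be computed. Without ``gene_list`` the intersection is used, ordered
    as in ``a``; a supplied ``gene_list`` is filtered to genes present on
    both sides (absent genes are dropped with a warning).
    """
    set_a, set_b = set(a.genes), set(b.genes)
    if gene_list is None:
        shared = [g for g in a.genes if g in set_b]
    else:
        shared = []
        for g in gene_list:
            if g in set_a and g in set_b:
                shared.append(g)
            else:
                logger.warning("gene %s absent from at least one trajectory; dropped", g)
    if not shared:
        raise ValueError("no genes shared between the two trajectories")
    return _subset_genes(a, shared), _subset_genes(b, shared)


def write_alignment(alignment, path: str | Path) -> None:
    """Write the chosen path as a TSV with 1-based matrix indices.

    Columns: ``index_a``, ``index_b``, ``cost``, ``kept``, ``segment_id``
    (segment of kept matches, -1 for pruned rows).
    """
    rows = []
    segment_of = {}
    for sid, segment in enumerate(alignment.segments, start=1):
        for match in segment:
            segment_of[match] = sid
    kept = set(alignment.kept_matches)
    for (i, j), c in zip(alignment.chosen.matches, alignment.chosen.match_costs):
        rows.append(
            {
                "index_a": i + 1,
                "index_b": j + 1,
                "cost": c,
                "kept": (i, j) in kept,
                "segment_id": segment_of.get((i, j), -1),
            }
        )
    frame = pd.DataFrame(rows, columns=["index_a", "index_b", "cost", "kept", "segment_id"])
    frame.to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path) -> pd.DataFrame:
    """Read back an alignment TSV written by :func:`write_alignment`."""
    return pd.read_csv(path, sep="\t")


def write_trajectory_csv(t: TrajectoryData, expression_path, pseudotime_path) -> None:
    """Write a trajectory as the dense-CSV + pseudotime-TSV pair."""
    pd.DataFrame(t.expression, index=t.genes, columns=t.cells).to_csv(
        expression_path, float_format="%.17g"
    )
    pd.DataFrame({"cell_id": t.cells, "pseudotime": t.pseudotime}).to_csv(
        pseudotime_path, sep="\t", index=False, float_format="%.17g"
    )
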