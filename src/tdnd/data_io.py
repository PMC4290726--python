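"""Expression-matrix and edge-list I/O, plus per-gene standardization.

Expression data are tab- or comma-separated text with a mandatory header.
The canonical in-memory orientation is rows = time points, columns = genes
(the T×N matrix X).  Networks travel as four-column TSV edge lists
(regulator, target, weight, lag); weight and lag may be empty for
ground-truth networks that carry topology only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DirectedNetwork",
    "load_expression",
    "normalize",
    "write_expression",
    "write_edge_list",
    "load_edge_list",
]


@dataclass
class ExpressionMatrix:
    """A T×N time-series expression matrix with gene names.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        Expression levels; rows are ordered time points, columns genes.
    gene_names : list of str
        N unique gene identifiers, one per column.
    time_labels : list, optional
        T labels for the rows (sampling times); purely descriptive.
    """

    values: np.ndarray
    gene_names: list[str]
    time_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        t, n = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 time points, got T={t}")
        if n < 2:
            raise ValueError(f"need at least 2 genes, got N={n}")
        self.gene_names = [str(g) for g in self.gene_names]
        if len(self.gene_names) != n:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n} columns"
            )
        dupes = {g for g in self.gene_names if self.gene_names.count(g) > 1}
        if dupes:
            raise ValueError(f"duplicate gene names: {sorted(dupes)}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.time_labels is not None and len(self.time_labels) != t:
            raise ValueError("time_labels length does not match T")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        idx = self.time_labels if self.time_labels is not None else None
        return pd.DataFrame(self.values, columns=self.gene_names, index=idx)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_names=[str(c) for c in df.columns],
            time_labels=list(df.index) if not isinstance(df.index, pd.RangeIndex) else None,
        )


class DirectedNetwork:
    """A directed network over a declared gene universe.

    Edges are ordered (regulator, target) pairs, optionally annotated with a
    real weight and a nonnegative integer lag.  Endpoints must belong to the
    universe; self-loops are allowed in the container but are excluded from
    evaluation.
    """

    def __init__(
        self,
        genes: Sequence[str],
        edges: Iterable[tuple] = (),
    ) -> None:
        self.genes = [str(g) for g in genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicates")
        self._gene_set = set(self.genes)
        self._edges: dict[tuple[str, str], tuple[float | None, int | None]] = {}
        for e in edges:
            self.add_edge(*e)

    def add_edge(
        self,
        regulator: str,
        target: str,
        weight: float | None = None,
        lag: int | None = None,
    ) -> None:
        regulator, target = str(regulator), str(target)
        for g in (regulator, target):
            if g not in self._gene_set:
                raise ValueError(f"gene {g!r} not in declared universe")
        if lag is not None:
            lag = int(lag)
            if lag < 0:
                raise ValueError(f"negative lag on edge {regulator}->{target}")
        self._edges[(regulator, target)] = (
            None if weight is None else float(weight),
            lag,
        )

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set as (regulator, target) pairs."""
        return set(self._edges)

    def weight(self, regulator: str, target: str) -> float | None:
        return self._edges[(regulator, target)][0]

    def lag(self, regulator: str, target: str) -> int | None:
        return self._edges[(regulator, target)][1]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return (
            set(self.genes) == set(other.genes)
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"DirectedNetwork({len(self.genes)} genes, {len(self._edges)} edges)"
        )


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _raw_header(path, sep) -> list[str]:
    # pandas mangles duplicate header names; keep the originals for checks
    with open(path) as fh:
        return [c.strip() for c in fh.readline().rstrip("\n").split(sep)]


def load_expression(
    path,
    orientation: str = "rows-are-timepoints",
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    ``rows-are-timepoints`` (canonical): one header line of gene names, each
    subsequent row a time point.  ``rows-are-genes``: first column holds gene
    names, header holds time labels; the table is transposed on load.
    Missing ("NA", empty) or non-numeric cells are rejected with the offending
    row and column named.
    """
    if orientation not in ("rows-are-timepoints", "rows-are-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    if orientation == "rows-are-genes":
        gene_names = raw.iloc[:, 0].tolist()
        time_labels = [str(c) for c in raw.columns[1:]]
        cells = raw.iloc[:, 1:]
        numeric = cells.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"missing or non-numeric value {cells.iat[r, c]!r} for gene "
                f"{gene_names[r]!r} at time column {time_labels[c]!r}"
            )
        values = numeric.to_numpy(dtype=float).T
    else:
        gene_names = _raw_header(path, sep)
        time_labels = None
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"missing or non-numeric value {raw.iat[r, c]!r} at data row "
                f"{r + 1}, gene column {gene_names[c]!r}"
            )
        values = numeric.to_numpy(dtype=float)
    xm = ExpressionMatrix(values, gene_names, time_labels)
    logger.info(
        "loaded expression matrix: T=%d time points, N=%d genes",
        xm.n_timepoints,
        xm.n_genes,
    )
    return xm


def write_expression(xm: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV in canonical orientation."""
    xm.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def normalize(xm: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every gene to zero mean and unit standard deviation.

    Uses the sample standard deviation (T−1 denominator).  A gene with zero
    variance across time is a hard error: it carries no usable signal and
    silently dropping it would desynchronise gene indices in every output.
    """
    v = xm.values
    sd = v.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [xm.gene_names[i] for i in constant]
        raise ValueError(f"constant gene (zero variance): {names}")
    z = (v - v.mean(axis=0)) / sd
    return ExpressionMatrix(z, list(xm.gene_names), xm.time_labels)


_EDGE_HEADER = ["regulator", "target", "weight", "lag"]


def write_edge_list(net, path) -> None:
    """Write edges as a TSV with columns regulator, target, weight, lag.

    Accepts a :class:`DirectedNetwork` or any iterable of edge tuples/records
    with fields (regulator, target, weight, lag).  None weights/lags are
    written as empty cells.
    """
    if isinstance(net, DirectedNetwork):
        rows = [
            (r, t, net.weight(r, t), net.lag(r, t))
            for (r, t) in sorted(net.edges)
        ]
    else:
        rows = [tuple(e)[:4] for e in net]
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for reg, tgt, w, lag in rows:
            wcell = "" if w is None else f"{float(w):.10g}"
            lcell = "" if lag is None else str(int(lag))
            fh.write(f"{reg}\t{tgt}\t{wcell}\t{lcell}\n")


def load_edge_list(path, universe: Sequence[str] | None = None) -> DirectedNetwork:
    """Read a directed edge list; validate endpoints against ``universe``.

    Without an explicit universe the union of endpoint names is used.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), header=0, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["regulator", "target"]:
        raise ValueError(
            f"edge list must start with columns 'regulator', 'target'; got {cols}"
        )
    regs = df.iloc[:, 0].astype(str)
    tgts = df.iloc[:, 1].astype(str)
    weights = (
        pd.to_numeric(df["weight"], errors="coerce") if "weight" in cols else None
    )
    lags = pd.to_numeric(df["lag"], errors="coerce") if "lag" in cols else None
    if universe is None:
        universe = sorted(set(regs) | set(tgts))
    net = DirectedNetwork(universe)
    for k in range(len(df)):
        w = None
        if weights is not None and not pd.isna(weights.iloc[k]):
            w = float(weights.iloc[k])
        l = None
        if lags is not None and not pd.isna(lags.iloc[k]):
            l = int(lags.iloc[k])
        net.add_edge(regs.iloc[k], tgts.iloc[k], w, l)
    return net
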