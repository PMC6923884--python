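"""On-disk formats: expression TSV, outcome TSV, graphs, feature matrices.

Expression files follow the GEO series-matrix convention: tab-separated,
features in rows, samples in columns, first column the feature id, first row
the sample ids, with optional '!'-prefixed comment/header lines that are
skipped. Missing-value tokens are the empty field, "NA", "NaN" and "null"
(case-insensitive); features containing any missing value are dropped on load.

Graphs are written as GraphML (with beta and fit_r2 graph attributes) or as a
3-column (u, v, weight) edge list. Floats are written with ``repr`` so
write -> read round-trips are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from psntopo.psn import PatientGraph

MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


@dataclass
class ExpressionMatrix:
    """Features x samples real matrix with unique feature and sample ids."""

    values: np.ndarray  # (p, n)
    feature_ids: list[str]
    sample_ids: list[str]
    platform_tag: str = ""
    n_dropped: int = 0  # features removed because of missing values

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression values must be 2-D (features x samples)")
        p, n = v.shape
        if p < 1 or n < 2:
            raise ValueError(f"need p >= 1 features and n >= 2 samples, got {p} x {n}")
        if np.isnan(v).any():
            raise ValueError("expression matrix contains missing values after loading")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} id(s): {dups}")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def profiles(self) -> np.ndarray:
        """Samples x features view (the orientation the pipeline works in)."""
        return self.values.T

    def subset_features(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            self.values[idx, :], [self.feature_ids[i] for i in idx],
            list(self.sample_ids), self.platform_tag,
        )


@dataclass
class OutcomeTable:
    """Binary clinical outcome labels (absence/presence of event) per sample."""

    sample_ids: list[str]
    outcomes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in outcome table")
        clean = {}
        for name, y in self.outcomes.items():
            y = np.asarray(y)
            if y.shape != (n,):
                raise ValueError(f"outcome '{name}' length mismatch")
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"outcome '{name}' has non-binary values")
            clean[name] = y.astype(int)
        self.outcomes = clean

    def labels(self, outcome_name: str) -> np.ndarray:
        if outcome_name not in self.outcomes:
            raise KeyError(
                f"unknown outcome '{outcome_name}'; available: {sorted(self.outcomes)}"
            )
        return self.outcomes[outcome_name]

    def aligned_to(self, sample_ids: Sequence[str]) -> "OutcomeTable":
        """Reorder to ``sample_ids``; error listing any sample without labels."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples without outcome labels: {missing}")
        idx = [pos[s] for s in sample_ids]
        return OutcomeTable(
            list(sample_ids), {k: v[idx] for k, v in self.outcomes.items()}
        )


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips; integers bit-exact."""
    f = float(x)
    if f.is_integer() and abs(f) < 1e16:
        return str(int(f))
    return repr(f)


def read_expression_matrix(
    path, drop_missing: bool = True, platform_tag: str = ""
) -> ExpressionMatrix:
    """Read a features x samples expression TSV (series-matrix dialect).

    Lines starting with '!' are skipped. Rows containing any recognized
    missing token are dropped when ``drop_missing`` is set (the count is
    recorded in ``n_dropped``); otherwise a missing cell is a hard error.
    A non-numeric cell that is not a missing token is a hard error naming the
    row and column.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("!")]
    if not lines:
        raise ValueError(f"{path}: no table content")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s): {dups}")
    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    n = len(sample_ids)
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        fid, cells = parts[0], parts[1:]
        if len(cells) != n:
            raise ValueError(f"{path}: row '{fid}' has {len(cells)} cells, expected {n}")
        vals = np.empty(n)
        has_missing = False
        for j, c in enumerate(cells):
            token = c.strip().strip('"')
            if token.lower() in MISSING_TOKENS:
                has_missing = True
                vals[j] = np.nan
                continue
            try:
                vals[j] = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value '{c}' at row '{fid}', "
                    f"column '{sample_ids[j]}'"
                ) from None
        if has_missing:
            if drop_missing:
                n_dropped += 1
                continue
            raise ValueError(f"{path}: missing value in row '{fid}'")
        feature_ids.append(fid)
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: all features dropped")
    return ExpressionMatrix(
        np.vstack(rows), feature_ids, sample_ids, platform_tag, n_dropped
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_outcomes(path, outcome_names: Sequence[str] | None = None) -> OutcomeTable:
    """Read an outcome TSV (sample id column + one {0,1} column per outcome).

    Columns not in ``outcome_names`` are ignored; requesting an unknown
    outcome is an error naming the available columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_ids = df.iloc[:, 0].tolist()
    available = list(df.columns[1:])
    names = list(outcome_names) if outcome_names is not None else available
    unknown = [n for n in names if n not in available]
    if unknown:
        raise ValueError(f"unknown outcome(s) {unknown}; available: {available}")
    outcomes = {}
    for name in names:
        col = df[name]
        try:
            y = col.astype(float).to_numpy()
        except ValueError:
            raise ValueError(f"outcome '{name}' has non-numeric values") from None
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"outcome '{name}' has non-binary values")
        outcomes[name] = y.astype(int)
    return OutcomeTable(sample_ids, outcomes)


def write_outcomes(table: OutcomeTable, path) -> None:
    with open(path, "w", newline="\n") as fh:
        names = list(table.outcomes)
        fh.write("sample_id\t" + "\t".join(names) + "\n")
        for i, sid in enumerate(table.sample_ids):
            fh.write(sid + "\t" + "\t".join(str(int(table.outcomes[n][i])) for n in names) + "\n")


def write_graph(graph: PatientGraph, path, format: str = "graphml") -> None:
    """Write a PatientGraph as GraphML or a (u, v, weight) edge list."""
    if format == "graphml":
        import networkx as nx

        g = graph.to_networkx()
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w", newline="\n") as fh:
            fh.write(f"# beta={_fmt(graph.beta)}\tfit_r2={repr(float(graph.fit_r2))}\n")
            n = graph.n
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(
                        f"{graph.sample_ids[i]}\t{graph.sample_ids[j]}\t"
                        f"{repr(float(graph.weights[i, j]))}\n"
                    )
    else:
        raise ValueError(f"unknown graph format '{format}' (use graphml or edgelist)")


def read_graph(path, format: str = "graphml") -> PatientGraph:
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        ids = list(g.nodes())
        pos = {s: i for i, s in enumerate(ids)}
        n = len(ids)
        w = np.zeros((n, n))
        for u, v, d in g.edges(data=True):
            w[pos[u], pos[v]] = w[pos[v], pos[u]] = float(d["weight"])
        beta = float(g.graph.get("beta", 1.0))
        fit_r2 = float(g.graph.get("fit_r2", float("nan")))
        return PatientGraph(w, beta, ids, fit_r2)
    if format == "edgelist":
        beta, fit_r2 = 1.0, float("nan")
        edges: list[tuple[str, str, float]] = []
        for ln in Path(path).read_text().splitlines():
            if ln.startswith("#"):
                for tok in ln[1:].split("\t"):
                    key, _, val = tok.strip().partition("=")
                    if key == "beta":
                        beta = float(val)
                    elif key == "fit_r2":
                        fit_r2 = float(val)
                continue
            u, v, wt = ln.split("\t")
            edges.append((u, v, float(wt)))
        ids: list[str] = []
        for u, v, _ in edges:
            for s in (u, v):
                if s not in ids:
                    ids.append(s)
        pos = {s: i for i, s in enumerate(ids)}
        w = np.zeros((len(ids), len(ids)))
        for u, v, wt in edges:
            w[pos[u], pos[v]] = w[pos[v], pos[u]] = wt
        return PatientGraph(w, beta, ids, fit_r2)
    raise ValueError(f"unknown graph format '{format}' (use graphml or edgelist)")


def write_feature_matrix(values: np.ndarray, feature_names: Sequence[str],
                         sample_ids: Sequence[str], path) -> None:
    """Samples x features TSV with a header row."""
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(feature_names) + "\n")
        for sid, row in zip(sample_ids, np.asarray(values, dtype=float)):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (values samples x features, feature_names, sample_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index]
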