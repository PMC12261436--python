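"""Readers, writers and run configuration.

TSV is the canonical on-disk format; CSV is accepted by sniffing the
delimiter.  Expression matrices carry sample ids (rows) and gene ids
(columns); networks are 3-column edge lists (``source target weight``)
with an optional auto-detected header, or square labeled adjacency
matrices; metadata tables have a sample-id first column and numeric or
categorical annotation columns (categoricals are one-hot expanded in
lexicographic level order).  All writers are deterministic and numbers
are serialized with 12 significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factorization import FactorModel
from .graphs import GeneRegulatoryNetwork

logger = logging.getLogger("grackle")

FLOAT_FORMAT = "%.12g"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


@dataclass
class RunConfig:
    """Resolved parameters of a CLI run; serialized beside every output."""

    command: str
    expression: str | None = None
    metadata: str | None = None
    network: str | None = None
    out: str | None = None
    k: int | None = None
    lambda1: float | None = None
    lambda2: float | None = None
    lambda1_grid: list[float] | None = None
    lambda2_grid: list[float] | None = None
    n_iterations: int | None = None
    metric: str | None = None
    mode: str | None = None
    alpha: float = 0.05
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0
    orientation: str = "auto"
    zero_ss_diagonal: bool = False
    top_var: int | None = None
    minmax: bool = False
    extra: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "resolved_config.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_expression(
    path: str | Path,
    orientation: str = "auto",
    top_var: int | None = None,
    minmax: bool = False,
    allow_negative_then_shift: bool = False,
) -> pd.DataFrame:
    """Load a samples x genes expression table.

    ``orientation='auto'`` takes the table as samples x genes (rows are
    samples); ``genes_by_samples`` transposes.  Optional processing, in
    order: keep the ``top_var`` highest-variance genes, then per-gene
    min-max scale.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0).astype(float)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column identifiers")
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation not in ("auto", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=float)
    if values.min() < 0:
        if not allow_negative_then_shift:
            raise ValueError(
                f"{path}: negative expression values (use "
                "allow_negative_then_shift to shift to nonnegative)"
            )
        df = df - values.min()
    if top_var is not None:
        variances = df.var(axis=0)
        keep = variances.sort_values(ascending=False, kind="stable").index[:top_var]
        df = df[[c for c in df.columns if c in set(keep)]]
    if minmax:
        from .simulation import min_max_scale

        df = pd.DataFrame(
            min_max_scale(df.to_numpy(dtype=float)),
            index=df.index, columns=df.columns,
        )
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load sample metadata; categoricals one-hot expanded, NaN -> 0.

    One-hot columns are named ``column=level`` with levels in
    lexicographic order; missing values contribute no similarity and
    their count is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    out = {}
    n_missing = int(df.isna().sum().sum())
    for col in df.columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.fillna(0.0).astype(float)
        else:
            for level in sorted(series.dropna().astype(str).unique()):
                out[f"{col}={level}"] = (
                    (series.astype(str) == level).astype(float)
                )
    if n_missing:
        logger.info("read_metadata: %d missing values replaced with 0", n_missing)
    return pd.DataFrame(out, index=df.index)


def read_network(path: str | Path, merge_duplicates: bool = False) -> GeneRegulatoryNetwork:
    """Load a GRN from an edge-list TSV or a labeled adjacency matrix.

    Edge lists are ``source target weight`` with an optional header
    (auto-detected from a non-numeric weight field).  A square table
    whose row and column labels coincide is read as an adjacency matrix.
    Duplicate (source, target) pairs are an error unless
    ``merge_duplicates``, which keeps the maximum weight.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    probe = pd.read_csv(path, sep=sep, header=None, nrows=2)
    if probe.shape[1] > 3:
        adj = pd.read_csv(path, sep=sep, index_col=0)
        if adj.shape[0] == adj.shape[1] and list(adj.index) == list(adj.columns):
            nodes = [str(n) for n in adj.index]
            M = adj.to_numpy(dtype=float)
            edges = [
                (nodes[i], nodes[j], float(M[i, j]))
                for i in range(len(nodes)) for j in range(len(nodes))
                if M[i, j] != 0
            ]
            return GeneRegulatoryNetwork(nodes=nodes, edges=edges)
        raise ValueError(f"{path}: not an edge list and not a square adjacency matrix")
    # header detection: third field of the first row numeric?
    has_header = False
    try:
        float(probe.iloc[0, 2])
    except (TypeError, ValueError):
        has_header = True
    df = pd.read_csv(
        path, sep=sep, header=0 if has_header else None,
        names=["source", "target", "weight"],
        skiprows=0,
    )
    edges_map: dict[tuple[str, str], float] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2 if has_header else 1):
        try:
            s, t, w = str(row.source), str(row.target), float(row.weight)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed edge line") from exc
        if (s, t) in edges_map:
            if not merge_duplicates:
                raise ValueError(f"{path}:{lineno}: duplicate edge ({s}, {t})")
            edges_map[(s, t)] = max(edges_map[(s, t)], w)
        else:
            edges_map[(s, t)] = w
    nodes = sorted({n for st in edges_map for n in st})
    edges = [(s, t, w) for (s, t), w in sorted(edges_map.items())]
    return GeneRegulatoryNetwork(nodes=nodes, edges=edges)


def write_network(grn: GeneRegulatoryNetwork, path: str | Path) -> None:
    df = pd.DataFrame(sorted(grn.edges), columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_similarity(matrix: np.ndarray, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT
    )


def write_model(
    model: FactorModel,
    out_dir: str | Path,
    sample_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> None:
    """Write W.tsv, H.tsv and fit_report.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, k = model.W.shape
    n = model.H.shape[1]
    samples = sample_ids if sample_ids is not None else [f"s{i}" for i in range(m)]
    genes = gene_ids if gene_ids is not None else [f"g{j}" for j in range(n)]
    lvs = [f"LV{i + 1}" for i in range(k)]
    pd.DataFrame(model.W, index=samples, columns=lvs).to_csv(
        out / "W.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    pd.DataFrame(model.H, index=lvs, columns=genes).to_csv(
        out / "H.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    report = {
        "k": model.k, "lambda1": model.lambda1, "lambda2": model.lambda2,
        "seed": model.seed, "n_iter": model.n_iter,
        "converged": model.converged, "final_loss": model.final_loss,
        "loss_history": model.loss_history,
    }
    (out / "fit_report.json").write_text(json.dumps(report, indent=2) + "\n")


def read_factor_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0)


def setup_run_logging(out_dir: str | Path) -> logging.Handler:
    """Attach a timestamped run.log file handler to the package logger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler
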