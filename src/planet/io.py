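"""File formats, configuration and the metacell aggregation utility.

Expression travels as CSV/TSV (cells x genes, gene-name header) or
MatrixMarket with gene/cell sidecars; networks as two-column TSV edge
lists with a gene-role sidecar.  Gene identity is name-based: loaders
re-index matrices to a canonical sorted gene order so that any two
objects over the same gene universe align.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import GRN, ExpressionMatrix

__all__ = ["read_expression", "write_expression", "read_edges", "write_edges",
           "write_probabilities", "read_gene_roles", "write_gene_roles",
           "metacell_aggregate", "write_manifest", "get_logger"]

log = logging.getLogger("planet")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level.upper())
    return log


class ParseError(ValueError):
    pass


def _canonical(expr: ExpressionMatrix) -> ExpressionMatrix:
    return expr.reorder(sorted(expr.genes))


def read_expression(path, fmt: str | None = None,
                    canonical_order: bool = True) -> ExpressionMatrix:
    """Load a cells x genes matrix from CSV, TSV or MatrixMarket.

    MTX input expects ``<stem>.genes.txt`` and ``<stem>.cells.txt``
    sidecars (one name per line); the matrix is cells x genes.
    """
    path = Path(path)
    fmt = fmt or {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
        path.suffix.lower())
    if fmt is None:
        raise ParseError(f"cannot infer format from {path.name}")
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dups = [g for g in header if header.count(g) > 1]
        if dups:
            raise ParseError(f"{path}: duplicated gene names {sorted(set(dups))[:5]}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        def _non_numeric(v) -> bool:
            try:
                float(v)
                return False
            except (TypeError, ValueError):
                return True

        bad = df.map(_non_numeric).to_numpy()
        if bad.any():
            row = int(bad.any(axis=1).argmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric value near line {row}")
        expr = ExpressionMatrix(df.to_numpy(dtype=float),
                                [str(c) for c in df.columns],
                                [str(i) for i in df.index])
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes_path = path.with_suffix("").with_suffix(".genes.txt")
        cells_path = path.with_suffix("").with_suffix(".cells.txt")
        for side in (genes_path, cells_path):
            if not side.exists():
                raise ParseError(f"missing sidecar {side.name} for {path.name}")
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=float)
        if dense.shape != (len(cells), len(genes)):
            raise ParseError(
                f"{path}: matrix is {dense.shape} but sidecars give "
                f"{len(cells)} cells ({cells_path.name}) x {len(genes)} genes "
                f"({genes_path.name})")
        expr = ExpressionMatrix(dense, genes, cells)
    else:
        raise ParseError(f"unknown format {fmt!r}")
    return _canonical(expr) if canonical_order else expr


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
        path.suffix.lower(), "csv")
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(expr.values, index=expr.cells,
                     columns=expr.genes).to_csv(path, sep=sep)
    else:
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.values))
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(expr.genes) + "\n")
        path.with_suffix("").with_suffix(".cells.txt").write_text(
            "\n".join(expr.cells) + "\n")


def read_gene_roles(path) -> tuple[list[str], np.ndarray]:
    """Gene-role TSV (gene_name, is_tf 0/1) -> (genes, tf_mask), sorted."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "is_tf"])
    df = df.sort_values("gene", kind="stable")
    return df["gene"].astype(str).tolist(), df["is_tf"].astype(int).to_numpy() == 1


def write_gene_roles(grn: GRN, path) -> None:
    pd.DataFrame({"gene": grn.genes,
                  "is_tf": grn.tf_mask.astype(int)}).to_csv(
        path, sep="\t", header=False, index=False)


def read_edges(path, genes: list[str], tf_mask: np.ndarray) -> GRN:
    """Two-column TSV edge list (regulator, target) -> GRN over ``genes``."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["regulator", "target"], usecols=[0, 1])
    index = {g: i for i, g in enumerate(genes)}
    unknown = sorted({g for col in ("regulator", "target")
                      for g in df[col].astype(str) if g not in index})
    if unknown:
        raise ParseError(f"{path}: unknown gene names {unknown[:5]}")
    selfed = df[df["regulator"] == df["target"]]
    if len(selfed):
        raise ParseError(
            f"{path}: self-regulatory edge {selfed.iloc[0, 0]!r} is not "
            f"allowed (no-self-edge rule)")
    adj = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for reg, tgt in zip(df["regulator"], df["target"]):
        adj[index[str(reg)], index[str(tgt)]] = 1
    return GRN(genes=list(genes), tf_mask=np.asarray(tf_mask, bool), adjacency=adj)


def write_edges(grn: GRN, path) -> None:
    pd.DataFrame(grn.edge_list(), columns=["regulator", "target"]).to_csv(
        path, sep="\t", header=False, index=False)


def write_probabilities(probs: np.ndarray, genes: list[str], path,
                        min_prob: float = 0.0) -> None:
    """Edge probabilities as TSV (regulator, target, probability), descending."""
    probs = np.asarray(probs)
    rows = [(genes[i], genes[j], float(probs[i, j]))
            for i, j in zip(*np.nonzero(probs > min_prob))]
    rows.sort(key=lambda r: -r[2])
    pd.DataFrame(rows, columns=["regulator", "target", "probability"]).to_csv(
        path, sep="\t", header=False, index=False)


def metacell_aggregate(expr: ExpressionMatrix, n_metacells: int,
                       seed: int = 0) -> ExpressionMatrix:
    """Average similar cells into metacells (k-means on normalized cells).

    A lightweight stand-in for heavier metacell pipelines: cells are
    library-size normalized and log-transformed, clustered with k-means,
    and each metacell is the mean raw expression of its members.
    """
    from sklearn.cluster import KMeans

    if n_metacells > expr.n_cells:
        raise ValueError(
            f"n_metacells={n_metacells} exceeds cell count {expr.n_cells}")
    v = expr.values
    libs = v.sum(axis=1, keepdims=True)
    norm = np.log1p(v / np.where(libs > 0, libs, 1.0) * 1e4)
    km = KMeans(n_clusters=n_metacells, random_state=seed, n_init=10)
    labels = km.fit_predict(norm)
    out = np.zeros((n_metacells, expr.n_genes))
    rng = np.random.default_rng(seed)
    for c in range(n_metacells):
        members = labels == c
        if members.sum() == 0:  # re-seed an empty cluster from a random cell
            out[c] = v[rng.integers(expr.n_cells)]
        else:
            out[c] = v[members].mean(axis=0)
    return ExpressionMatrix(out, list(expr.genes),
                            [f"metacell{c}" for c in range(n_metacells)])


def write_manifest(out_dir, config: dict, seed: int,
                   inputs: dict[str, Path] | None = None) -> Path:
    """Record config hash, seed, versions and input checksums for a run."""
    import planet

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, p in (inputs or {}).items():
        checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "versions": {"planet": planet.__version__, "numpy": np.__version__},
        "input_checksums": checksums,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
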