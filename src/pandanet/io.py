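"""Readers and writers for the tool's tabular formats, plus run manifests.

Formats:

* motif / PPI priors — headerless 3-column TSV ``id <tab> id <tab> weight``;
* expression — TSV with a sample-name header row and gene identifiers in
  the first column;
* networks — either a 4-column edge list TSV (TF, gene, prior weight,
  final weight; sorted by TF then gene) or a dense HDF5 container with
  ``tf_ids`` / ``gene_ids`` / ``weights`` datasets.

Missing values are never imputed: a malformed cell is an error naming its
line.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .panda import RegulatoryNetwork
from .preprocess import ExpressionMatrix

__all__ = [
    "read_prior",
    "read_expression",
    "read_matrix_tsv",
    "write_prior",
    "write_expression",
    "write_network",
    "read_network_dense",
    "RunManifest",
    "file_digest",
]


def read_prior(path: str) -> list[tuple[str, str, float]]:
    """Read a headerless 3-column edge-list TSV."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            a, b, w = parts
            if not a.strip() or not b.strip():
                raise ValueError(f"{path}:{lineno}: blank identifier")
            try:
                weight = float(w)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {w!r}") from None
            if not np.isfinite(weight):
                raise ValueError(f"{path}:{lineno}: non-finite weight {w!r}")
            edges.append((a, b, weight))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return edges


def _parse_table(path: str) -> tuple[list[str], list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}:1: missing header row")
        col_ids = header.split("\t")[1:]
        if not col_ids:
            raise ValueError(f"{path}:1: header has no sample/column names")
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(col_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row — expected {len(col_ids) + 1} "
                    f"columns, got {len(parts)}"
                )
            rid = parts[0]
            if rid in row_ids:
                raise ValueError(f"{path}:{lineno}: duplicate identifier {rid!r}")
            vals = []
            for c, cell in enumerate(parts[1:], start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {c}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(f"{path}:{lineno}: non-finite cell {cell!r}")
                vals.append(v)
            row_ids.append(rid)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return row_ids, col_ids, np.asarray(rows, dtype=float)


def read_expression(path: str) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV (header = sample names)."""
    gene_ids, sample_ids, values = _parse_table(path)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def read_matrix_tsv(path: str) -> tuple[list[str], list[str], np.ndarray]:
    """Read a generic labelled matrix TSV (row ids in the first column)."""
    return _parse_table(path)


def write_prior(edges, path: str) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:g}\n")


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_network(net: RegulatoryNetwork, path: str, format: str = "edge_tsv",
                  prior: np.ndarray | None = None) -> None:
    """Write a fitted network as a sorted edge list or a dense HDF5 container."""
    W = np.asarray(net.weights)
    if not np.all(np.isfinite(W)):
        raise ValueError("network weights contain non-finite values")
    if format == "edge_tsv":
        P0 = np.zeros_like(W, dtype=float) if prior is None else np.asarray(prior)
        if P0.shape != W.shape:
            raise ValueError("prior shape does not match weights")
        order_tf = np.argsort(net.tf_ids, kind="stable")
        order_g = np.argsort(net.gene_ids, kind="stable")
        with open(path, "w") as fh:
            for ti in order_tf:
                for gi in order_g:
                    fh.write(
                        f"{net.tf_ids[ti]}\t{net.gene_ids[gi]}\t"
                        f"{P0[ti, gi]:g}\t{float(W[ti, gi])!r}\n"
                    )
    elif format == "dense":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("tf_ids", data=np.array(net.tf_ids, dtype="S"))
            f.create_dataset("gene_ids", data=np.array(net.gene_ids, dtype="S"))
            f.create_dataset("weights", data=W)
            if prior is not None:
                f.create_dataset("prior", data=np.asarray(prior))
            f.attrs["converged"] = bool(net.converged)
            f.attrs["iterations_used"] = int(net.iterations_used)
    else:
        raise ValueError(f"unknown network format {format!r} (edge_tsv or dense)")


def read_network_dense(path: str) -> RegulatoryNetwork:
    import h5py

    with h5py.File(path, "r") as f:
        return RegulatoryNetwork(
            tf_ids=[x.decode() for x in f["tf_ids"][()]],
            gene_ids=[x.decode() for x in f["gene_ids"][()]],
            weights=f["weights"][()],
            iterations_used=int(f.attrs.get("iterations_used", 0)),
            converged=bool(f.attrs.get("converged", False)),
        )


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Flat key-value record of one invocation, written atomically."""

    command: str
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    peak_memory_mb: float | None = None
    output_paths: list[str] = field(default_factory=list)
    convergence: dict = field(default_factory=dict)

    def rows(self) -> list[tuple[str, str]]:
        out = [("command", self.command)]
        out += [(f"config.{k}", str(v)) for k, v in self.config.items()]
        out += [(f"input_digest.{k}", v) for k, v in self.input_digests.items()]
        out += [(f"seconds.{k}", f"{v:.6f}") for k, v in self.stage_seconds.items()]
        if self.peak_memory_mb is not None:
            out.append(("peak_memory_mb", f"{self.peak_memory_mb:.1f}"))
        out += [("output", p) for p in self.output_paths]
        out += [(f"convergence.{k}", str(v)) for k, v in self.convergence.items()]
        return out

    def write(self, path: str) -> None:
        d = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                for k, v in self.rows():
                    fh.write(f"{k}\t{v}\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @staticmethod
    def read(path: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                k, _, v = line.rstrip("\n").partition("\t")
                out.setdefault(k, []).append(v)
        return out
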