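"""Compute-backend contract: precision, staging, symmetric storage, checkpoints.

The message-passing engine is written against a small array-operations
surface — stage inputs once, compute pairwise similarities, fetch the final
result once — so an alternative execution strategy can be dropped in without
touching algorithm code.  Two backends ship:

``reference``
    Plain NumPy; the oracle every other backend must match.
``tiled``
    Computes pairwise similarity in fixed-size row blocks.  Blocked BLAS
    changes floating-point summation order, so it is a genuine (if modest)
    test of the backend-equivalence contract rather than an alias of the
    reference path.

The transfer policy mirrors an accelerator's host/device boundary: inputs
are staged exactly once and the result is fetched exactly once per run;
instrumentation counts both so tests can assert the policy.  Symmetric
gene-by-gene matrices may be held as one triangular half plus diagonal,
halving bytes at rest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .similarity import METRICS, pairwise_similarity

__all__ = [
    "BackendHandle",
    "ReferenceBackend",
    "TiledBackend",
    "get_backend",
    "StagedInputs",
    "SymmetricHalf",
    "CapacityError",
    "stage_inputs",
    "set_precision",
    "save_checkpoint",
    "restore_checkpoint",
    "Checkpoint",
]

_DTYPES = {"single": np.float32, "double": np.float64}


class CapacityError(RuntimeError):
    """Raised when a staged matrix would exceed the backend's capacity."""


def set_precision(M: np.ndarray, precision: str) -> np.ndarray:
    """Round an array to the requested floating-point width."""
    if precision not in _DTYPES:
        raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")
    return np.asarray(M, dtype=_DTYPES[precision])


class SymmetricHalf:
    """A symmetric matrix stored as its upper triangle plus diagonal.

    Reading entry (i, j) or (j, i) returns the same value either way.
    """

    def __init__(self, M: np.ndarray):
        M = np.asarray(M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("SymmetricHalf requires a square matrix")
        self.n = M.shape[0]
        self._iu = np.triu_indices(self.n)
        self.packed = M[self._iu].copy()

    @property
    def nbytes(self) -> int:
        return self.packed.nbytes

    def _flat(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        # offset of row i in the packed upper triangle, then column shift
        return i * self.n - (i * (i - 1)) // 2 + (j - i)

    def __getitem__(self, key: tuple[int, int]):
        i, j = key
        return self.packed[self._flat(i, j)]

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n), dtype=self.packed.dtype)
        out[self._iu] = self.packed
        out.T[self._iu] = self.packed
        return out


@dataclass
class BackendHandle:
    """Selects a compute backend, its precision, and optional limits.

    Parameters
    ----------
    kind : {"reference", "tiled"}
    precision : {"single", "double"}
    device_count : int
        Number of logical workers the handle represents (>= 1).
    checkpoint_path : str, optional
        Where :func:`save_checkpoint` writes snapshots.
    memory_limit : int, optional
        Capacity in bytes enforced at staging time; ``None`` means
        unlimited.
    """

    kind: str = "reference"
    precision: str = "double"
    device_count: int = 1
    checkpoint_path: Optional[str] = None
    memory_limit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("reference", "tiled"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.precision not in _DTYPES:
            raise ValueError(f"precision must be 'single' or 'double', got {self.precision!r}")
        if self.device_count < 1:
            raise ValueError("device_count must be >= 1")

    @property
    def dtype(self):
        return _DTYPES[self.precision]


class ReferenceBackend:
    """Plain-NumPy execution; the oracle for every alternative backend."""

    kind = "reference"

    def __init__(self, handle: BackendHandle):
        self.handle = handle
        self.transfers_in = 0
        self.transfers_out = 0

    def stage(self, **arrays: np.ndarray) -> dict[str, np.ndarray]:
        """Place inputs on the compute side (one inbound transfer)."""
        self.transfers_in += 1
        return {k: set_precision(v, self.handle.precision) for k, v in arrays.items()}

    def fetch(self, arr: np.ndarray) -> np.ndarray:
        """Retrieve a result from the compute side (one outbound transfer)."""
        self.transfers_out += 1
        return np.asarray(arr)

    def pairwise(self, X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
        return pairwise_similarity(X, Y, metric)


class TiledBackend(ReferenceBackend):
    """Evaluates pairwise similarity in row blocks of fixed size."""

    kind = "tiled"

    def __init__(self, handle: BackendHandle, tile: int = 64):
        super().__init__(handle)
        self.tile = int(tile)

    def pairwise(self, X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
        X = np.atleast_2d(X)
        Y = np.atleast_2d(Y)
        name = str(metric).lower()
        if name == "standardized_euclidean":
            # the pooled per-coordinate scale is a global statistic; fix it
            # once over the full stacked input, then tile plain euclidean
            s = np.vstack([X, Y]).std(axis=0, ddof=1)
            inv = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
            X, Y, name = X * inv, Y * inv, "euclidean"
        out = np.empty((X.shape[0], Y.shape[0]), dtype=np.result_type(X, Y))
        for lo in range(0, X.shape[0], self.tile):
            hi = min(lo + self.tile, X.shape[0])
            out[lo:hi] = pairwise_similarity(X[lo:hi], Y, name)
        return out


def get_backend(handle: BackendHandle) -> ReferenceBackend:
    if handle.kind == "tiled":
        return TiledBackend(handle)
    return ReferenceBackend(handle)


@dataclass
class StagedInputs:
    """Inputs placed once on the compute side for a full run."""

    W: np.ndarray
    P: np.ndarray
    _C: object = None  # dense ndarray or SymmetricHalf

    @property
    def C(self) -> np.ndarray:
        if isinstance(self._C, SymmetricHalf):
            return self._C.to_dense()
        return self._C

    def C_entry(self, i: int, j: int) -> float:
        if isinstance(self._C, SymmetricHalf):
            return float(self._C[i, j])
        return float(self._C[i, j])


def stage_inputs(triple, handle: BackendHandle, backend: ReferenceBackend | None = None,
                 symmetric_half: bool = False) -> StagedInputs:
    """Place the W/P/C triple on the compute side, once.

    Enforces the handle's byte capacity (bytes = rows * cols * width per
    matrix) before any allocation, and optionally stores the symmetric
    gene-by-gene matrix as one triangular half plus diagonal.
    """
    backend = backend or get_backend(handle)
    width = np.dtype(handle.dtype).itemsize
    if handle.memory_limit is not None:
        for name, m in (("W", triple.W), ("P", triple.P), ("C", triple.C)):
            need = m.shape[0] * m.shape[1] * width
            if need > handle.memory_limit:
                raise CapacityError(
                    f"matrix {name} requires {need} bytes "
                    f"({m.shape[0]}*{m.shape[1]}*{width}) which exceeds the "
                    f"backend capacity of {handle.memory_limit} bytes"
                )
    staged = backend.stage(W=triple.W, P=triple.P, C=triple.C)
    C = SymmetricHalf(staged["C"]) if symmetric_half else staged["C"]
    return StagedInputs(W=staged["W"], P=staged["P"], _C=C)


# ---------------------------------------------------------------------------
# Checkpoint / restart


@dataclass
class Checkpoint:
    iteration: int
    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    digest: str


def config_digest(cfg, triple) -> str:
    """Digest binding a checkpoint to its configuration and inputs."""
    payload = {
        "alpha": cfg.alpha,
        "metric": cfg.metric,
        "tolerance": cfg.tolerance,
        "max_iter": cfg.max_iter,
        "precision": cfg.precision,
        "shape": [int(s) for s in triple.W.shape],
    }
    h = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
    for m in (triple.W, triple.P, triple.C):
        h.update(np.ascontiguousarray(m, dtype=np.float64).tobytes())
    return h.hexdigest()


def save_checkpoint(state, handle: BackendHandle, digest: str) -> str:
    """Snapshot the current W/P/C and iteration counter to HDF5."""
    import h5py

    if not handle.checkpoint_path:
        raise ValueError("handle has no checkpoint_path configured")
    with h5py.File(handle.checkpoint_path, "w") as f:
        f.attrs["iteration"] = int(state.iteration)
        f.attrs["digest"] = digest
        f.create_dataset("W", data=state.W)
        f.create_dataset("P", data=state.P)
        f.create_dataset("C", data=state.C)
    return handle.checkpoint_path


def restore_checkpoint(path: str, expected_digest: str | None = None) -> Checkpoint:
    """Load a snapshot; refuse to restore under a different configuration."""
    import h5py

    with h5py.File(path, "r") as f:
        cp = Checkpoint(
            iteration=int(f.attrs["iteration"]),
            W=f["W"][()],
            P=f["P"][()],
            C=f["C"][()],
            digest=str(f.attrs["digest"]),
        )
    if expected_digest is not None and cp.digest != expected_digest:
        raise ValueError(
            "checkpoint was written under a different configuration or inputs; "
            "refusing to restore"
        )
    return cp
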