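"""Per-residue embedding providers and their integration into node features.

A protein language model (PLM) maps an amino-acid sequence of length N
to a per-residue representation h' of shape (N, psi_PLM); the widely
used ESM-2 650M checkpoint has psi_PLM = 1280, which is the default
width here.  Real PLM access is an optional plugin behind the
``EmbeddingProvider`` interface and is never required: the bundled mock
provider produces deterministic pseudo-random rows that encode both
residue identity and position, which is all the pipeline contracts and
toy benchmarks need.

Integration modes follow the feature-injection recipe:

``replace``  h' replaces h outright (the default for residue-level graphs),
``concat``   h' is appended column-wise to h,
``add``      elementwise sum, requiring psi_h == psi_PLM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import NodeAlignmentError, ShapeError, ValidationError
from .seq_struct_align import SeqStructMapping
from .structure_io import SequenceRecord

__all__ = [
    "EmbeddingMatrix",
    "EmbeddingProvider",
    "MockEmbeddingProvider",
    "DEFAULT_WIDTH",
    "mock_embed",
    "integrate",
    "project_embedding",
    "save_embedding",
    "load_embedding",
]

DEFAULT_WIDTH = 1280


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue representation h' of shape (N, psi_PLM)."""

    values: np.ndarray
    provider_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ShapeError("embedding values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite embedding value")
        object.__setattr__(self, "values", v)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def psi_plm(self) -> int:
        return self.values.shape[1]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Deterministic sequence -> per-residue matrix interface.

    Contract: ``embed(seq)`` returns one row per input residue, and
    identical sequences yield identical matrices.  Real language-model
    plugins implement this protocol; nothing in the package imports
    model weights.
    """

    id: str
    width: int

    def embed(self, seq: str | SequenceRecord) -> EmbeddingMatrix: ...


def mock_embed(seq: str | SequenceRecord, width: int = DEFAULT_WIDTH,
               seed: int = 0) -> EmbeddingMatrix:
    """Deterministic stand-in for a language-model forward pass.

    Row i is a pseudo-random vector seeded from a hash of
    (seed, residue letter, position i), so the matrix encodes residue
    identity *and* sequence position, and repeated calls are bitwise
    identical.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValidationError("cannot embed an empty sequence")
    if width < 1:
        raise ValidationError("embedding width must be >= 1")
    rows = np.empty((len(s), width))
    for i, letter in enumerate(s.upper()):
        digest = hashlib.blake2b(
            f"{seed}|{i}|{letter}".encode(), digest_size=8
        ).digest()
        row_seed = int.from_bytes(digest, "little")
        rows[i] = np.random.default_rng(row_seed).standard_normal(width)
    return EmbeddingMatrix(values=rows, provider_id=f"mock-w{width}-s{seed}")


@dataclass
class MockEmbeddingProvider:
    """The bundled provider: ``mock_embed`` with a fixed (width, seed)."""

    width: int = DEFAULT_WIDTH
    seed: int = 0

    @property
    def id(self) -> str:
        return f"mock-w{self.width}-s{self.seed}"

    def embed(self, seq: str | SequenceRecord) -> EmbeddingMatrix:
        return mock_embed(seq, width=self.width, seed=self.seed)


def integrate(h: np.ndarray, h_prime: EmbeddingMatrix,
              mode: str = "replace") -> np.ndarray:
    """Combine graph features h with embedding rows h'.

    Raises a ``NodeAlignmentError`` on a row-count mismatch, which means
    the embedding was computed on a sequence that does not match the
    graph nodes: reconcile sequence and structure first
    (``seq_struct_align.reconcile`` + ``project_embedding``).
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ShapeError("h must be 2-D")
    if h.shape[0] != h_prime.n_residues:
        raise NodeAlignmentError(
            f"h has {h.shape[0]} rows but embedding has {h_prime.n_residues};"
            " run sequence/structure reconciliation before integrating"
        )
    if mode == "replace":
        return h_prime.values.copy()
    if mode == "concat":
        return np.hstack([h, h_prime.values])
    if mode == "add":
        if h.shape[1] != h_prime.psi_plm:
            raise ShapeError(
                f"mode='add' requires psi_h == psi_PLM, got {h.shape[1]}"
                f" != {h_prime.psi_plm}"
            )
        return h + h_prime.values
    raise ValidationError(f"unknown integration mode {mode!r}")


def project_embedding(h_prime: EmbeddingMatrix,
                      mapping: SeqStructMapping) -> EmbeddingMatrix:
    """Select the full-sequence embedding rows that survive reconciliation.

    Rows are taken at the mapped full-sequence positions, ordered by
    structure position, so the result has one row per structure residue.
    """
    full_pos = mapping.full_positions()
    if full_pos and max(full_pos) > h_prime.n_residues:
        raise IndexError(
            f"mapping references position {max(full_pos)} but embedding has"
            f" {h_prime.n_residues} rows"
        )
    idx = np.array(full_pos, dtype=int) - 1
    return EmbeddingMatrix(values=h_prime.values[idx],
                           provider_id=h_prime.provider_id)


def _cache_key(provider_id: str, seq: str) -> str:
    h = hashlib.sha256(seq.encode()).hexdigest()[:16]
    return f"{provider_id}-{h}"


def save_embedding(em: EmbeddingMatrix, seq: str, directory: str | Path) -> Path:
    """Cache an embedding as raw float64 + JSON header, keyed by
    (provider id, sequence hash)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    key = _cache_key(em.provider_id, seq)
    (directory / f"{key}.bin").write_bytes(em.values.tobytes())
    (directory / f"{key}.json").write_text(json.dumps({
        "provider_id": em.provider_id,
        "n_residues": em.n_residues,
        "psi_plm": em.psi_plm,
        "dtype": "float64",
    }))
    return directory / f"{key}.json"


def load_embedding(provider_id: str, seq: str,
                   directory: str | Path) -> EmbeddingMatrix | None:
    """Load a cached embedding, or None if absent."""
    directory = Path(directory)
    key = _cache_key(provider_id, seq)
    header_path = directory / f"{key}.json"
    if not header_path.exists():
        return None
    header = json.loads(header_path.read_text())
    raw = (directory / f"{key}.bin").read_bytes()
    values = np.frombuffer(raw, dtype=np.float64).reshape(
        header["n_residues"], header["psi_plm"]
    ).copy()
    return EmbeddingMatrix(values=values, provider_id=header["provider_id"])
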