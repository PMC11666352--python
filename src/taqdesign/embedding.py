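"""Fixed-length sequence representations by mean-pooled per-residue features.

The production systems this package models use a protein language model to
produce per-residue embeddings that are averaged into a sequence vector. Here
the backend is pluggable: the default ``mock`` backend derives a deterministic
pseudo-random feature vector for every (residue identity, position bucket,
flanking 3-mer) context, which yields mutation-sensitive, position-aware
embeddings with no model downloads. An ``external-plm`` adapter slot accepts
any callable mapping a sequence to a per-residue feature matrix, so a real
encoder can be dropped in without touching downstream code.

Pooling is always the arithmetic mean over residue positions (no special or
boundary tokens are included).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, MutableMapping, Sequence

import numpy as np

from .variants import ProteinSequence


class BackendUnavailableError(RuntimeError):
    """The requested embedding backend is not available."""


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration of the embedding backend.

    ``dim`` is the feature dimension (>= 8); ``seed`` fully determines the
    mock backend's feature table; ``bucket_size`` is the coarseness of the
    positional component of the mock features.
    """

    backend: str = "mock"
    dim: int = 64
    pooling: str = "mean"
    seed: int = 0
    bucket_size: int = 16
    model: str | None = None
    layer: int | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("mock", "external-plm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.dim < 8:
            raise ValueError("dim must be >= 8")
        if self.pooling != "mean":
            raise ValueError("only mean pooling is supported")

    def digest(self) -> str:
        payload = json.dumps({
            "backend": self.backend, "dim": self.dim, "pooling": self.pooling,
            "seed": self.seed, "bucket_size": self.bucket_size,
            "model": self.model, "layer": self.layer,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    sequence_digest: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")


@lru_cache(maxsize=200_000)
def _mock_feature(seed: int, dim: int, residue: str, bucket: int, kmer: str
                  ) -> np.ndarray:
    """Deterministic pseudo-random feature for one residue context."""
    digest = hashlib.blake2b(
        f"{seed}|{residue}|{bucket}|{kmer}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    vec = rng.standard_normal(dim)
    vec.flags.writeable = False
    return vec


def residue_features(seq: ProteinSequence, spec: EmbedderSpec) -> np.ndarray:
    """(L, dim) per-residue feature matrix of the mock backend.

    The feature at position i depends on the residue identity, the native
    position bucket, and the flanking 3-mer, so a substitution perturbs the
    rows at i-1, i, i+1 only.
    """
    if spec.backend != "mock":
        raise BackendUnavailableError(
            f"backend {spec.backend!r} has no built-in feature table")
    padded = "^" + seq.residues + "$"
    rows = np.empty((len(seq), spec.dim))
    for i, residue in enumerate(seq.residues):
        native = seq.numbering_offset + i
        kmer = padded[i:i + 3]
        rows[i] = _mock_feature(spec.seed, spec.dim, residue,
                                native // spec.bucket_size, kmer)
    return rows


ExternalBackend = Callable[[ProteinSequence], np.ndarray]
_EXTERNAL_BACKENDS: dict[str, ExternalBackend] = {}


def register_external_backend(name: str, fn: ExternalBackend) -> None:
    """Register a callable mapping a sequence to an (L, dim) feature matrix."""
    _EXTERNAL_BACKENDS[name] = fn


def embed_sequence(seq: ProteinSequence, spec: EmbedderSpec) -> EmbeddingVector:
    """Mean-pool per-residue features into a fixed-length sequence vector."""
    if spec.backend == "mock":
        matrix = residue_features(seq, spec)
    else:
        if spec.model not in _EXTERNAL_BACKENDS:
            raise BackendUnavailableError(
                f"external backend {spec.model!r} is not registered")
        matrix = np.asarray(_EXTERNAL_BACKENDS[spec.model](seq), dtype=float)
        if matrix.shape != (len(seq), spec.dim):
            raise ValueError(f"external backend returned shape {matrix.shape}, "
                             f"expected {(len(seq), spec.dim)}")
    return EmbeddingVector(matrix.mean(axis=0), seq.digest())


class DiskCache(MutableMapping):
    """Simple key -> vector store on disk (one .npy file per key)."""

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, key: tuple[str, str]) -> Path:
        return self.directory / f"{key[0][:32]}_{key[1][:16]}.npy"

    def __getitem__(self, key):
        path = self._path(key)
        if not path.exists():
            raise KeyError(key)
        return np.load(path)

    def __setitem__(self, key, value) -> None:
        np.save(self._path(key), np.asarray(value))

    def __delitem__(self, key) -> None:
        self._path(key).unlink()

    def __iter__(self):
        return iter(())

    def __len__(self) -> int:
        return len(list(self.directory.glob("*.npy")))


def embed_batch(seqs: Sequence[ProteinSequence], spec: EmbedderSpec,
                cache: MutableMapping | None = None) -> list[EmbeddingVector]:
    """Embed a batch; results are identical to per-sequence calls.

    ``cache`` maps (sequence digest, spec digest) to a stored vector. Corrupt
    cache entries are recomputed rather than raised.
    """
    spec_digest = spec.digest()
    out: list[EmbeddingVector] = []
    computed: dict[str, EmbeddingVector] = {}
    for seq in seqs:
        digest = seq.digest()
        if digest in computed:
            out.append(computed[digest])
            continue
        vec: EmbeddingVector | None = None
        if cache is not None:
            try:
                stored = np.asarray(cache[(digest, spec_digest)], dtype=float)
                if stored.shape == (spec.dim,) and np.all(np.isfinite(stored)):
                    vec = EmbeddingVector(stored, digest)
            except (KeyError, ValueError, OSError):
                vec = None
        if vec is None:
            vec = embed_sequence(seq, spec)
            if cache is not None:
                cache[(digest, spec_digest)] = vec.values
        computed[digest] = vec
        out.append(vec)
    return out


def embedding_matrix(seqs: Sequence[ProteinSequence], spec: EmbedderSpec,
                     cache: MutableMapping | None = None) -> np.ndarray:
    """(n, dim) matrix of pooled embeddings."""
    return np.vstack([e.values for e in embed_batch(seqs, spec, cache)])


def export_embeddings_tsv(names: Sequence[str], matrix: np.ndarray,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        dim = matrix.shape[1]
        fh.write("variant\t" + "\t".join(f"e{i}" for i in range(dim)) + "\n")
        for name, row in zip(names, matrix):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def import_embeddings_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    names = df["variant"].tolist()
    return names, df.drop(columns="variant").to_numpy(dtype=float)
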