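"""Even-coverage gapped k-mer hashing and sparse sequence encoding.

A gapped (k, r)-mer reads only r of the k positions in a window, so two
sequences that differ at unselected positions still collide — the
locality-sensitive property that lets a linear classifier generalize to
remote homologs. Picking the r-subsets uniformly at random covers window
positions unevenly unless many functions are drawn; instead the ensemble is
built with an LDPC-style (Gallager) round construction: each round is a
random permutation of the k positions split into floor(k/r) disjoint blocks
of r, so after any number of rounds no position is covered more than once
per round and total coverage across the ensemble differs by at most one
between any two positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GallagerHashEnsemble:
    """m position-selection functions over k-residue windows, r positions each."""

    k: int
    r: int
    m: int
    seed: int
    functions: tuple[tuple[int, ...], ...]
    alphabet: str = ALPHABET

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "r": self.r,
                "m": self.m,
                "seed": self.seed,
                "alphabet": self.alphabet,
                "functions": [list(f) for f in self.functions],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GallagerHashEnsemble":
        d = json.loads(text)
        return cls(
            k=d["k"],
            r=d["r"],
            m=d["m"],
            seed=d["seed"],
            functions=tuple(tuple(f) for f in d["functions"]),
            alphabet=d["alphabet"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GallagerHashEnsemble":
        return cls.from_json(Path(path).read_text())

    @property
    def n_features(self) -> int:
        return self.m * len(self.alphabet) ** self.r


def build_gallager_ensemble(k: int, r: int, m: int, seed: int) -> GallagerHashEnsemble:
    """Construct m even-coverage gapped k-mer selection functions.

    Rounds of a seeded random permutation of [0, k) split into floor(k/r)
    disjoint ascending blocks of size r (any remainder of size < r is
    dropped); rounds repeat until m functions exist, then truncate.
    """
    if k <= 0 or r <= 0 or r > k:
        raise ParameterError(f"need 1 <= r <= k, got k={k}, r={r}")
    if m < 1:
        raise ParameterError(f"need m >= 1, got m={m}")
    rng = np.random.default_rng(seed)
    functions: list[tuple[int, ...]] = []
    n_blocks = k // r
    coverage = np.zeros(k, dtype=np.int64)
    while len(functions) < m:
        # ascending current coverage, random among equals: a plain random
        # permutation on full rounds, and the least-covered positions first
        # when a round is cut short or k % r positions must be dropped —
        # this is what keeps the max-min <= 1 coverage guarantee exact
        perm = np.lexsort((rng.random(k), coverage))
        for b in range(n_blocks):
            block = perm[b * r : (b + 1) * r]
            functions.append(tuple(int(x) for x in np.sort(block)))
            coverage[block] += 1
            if len(functions) == m:
                break
    return GallagerHashEnsemble(k=k, r=r, m=m, seed=seed, functions=tuple(functions))


def coverage_histogram(ens: GallagerHashEnsemble) -> np.ndarray:
    """Number of functions covering each of the k window positions."""
    hist = np.zeros(ens.k, dtype=np.int64)
    for f in ens.functions:
        for p in f:
            hist[p] += 1
    return hist


@dataclass
class SparseFeatureVector:
    """Sparse count vector over the m * 20^r gapped k-mer feature space."""

    indices: np.ndarray  # sorted unique feature ids, int64
    counts: np.ndarray  # positive int64 counts, aligned with indices

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {int(i): int(c) for i, c in zip(self.indices, self.counts)}


_EMPTY = np.empty(0, dtype=np.int64)


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer: fixed, seedless integer mixing for feature folding
    z = x.astype(np.uint64)
    with np.errstate(over="ignore"):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        z = z ^ (z >> np.uint64(31))
    return z


def encode_sequence(
    seq: str,
    ens: GallagerHashEnsemble,
    fold_bits: int | None = None,
) -> SparseFeatureVector:
    """Encode an amino-acid fragment into gapped k-mer feature counts.

    Every k-residue window contributes one feature per hash function:
    feature id = j * 20^r + sum_i code(w[p_i]) * 20^i, with code() the rank
    in the canonical alphabet order and p_0 < ... < p_{r-1} the positions of
    function j. Windows containing any non-standard residue (B, Z, X, U, O,
    ...) are skipped for all functions. With ``fold_bits`` set, ids are
    folded to 2^fold_bits buckets through a fixed seedless integer mix;
    collisions are accepted.
    """
    k, r = ens.k, ens.r
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8) & 0x7F]
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return SparseFeatureVector(_EMPTY.copy(), _EMPTY.copy())
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = windows.min(axis=1) >= 0
    windows = windows[valid]
    if windows.shape[0] == 0:
        return SparseFeatureVector(_EMPTY.copy(), _EMPTY.copy())
    base = len(ens.alphabet)
    pow_r = base ** np.arange(r, dtype=np.int64)
    block = np.int64(base**r)
    ids_parts = []
    for j, pos in enumerate(ens.functions):
        idx = windows[:, list(pos)] @ pow_r
        ids_parts.append(idx + np.int64(j) * block)
    ids = np.concatenate(ids_parts)
    if fold_bits is not None:
        ids = (_mix64(ids) & np.uint64((1 << fold_bits) - 1)).astype(np.int64)
    uniq, cnt = np.unique(ids, return_counts=True)
    return SparseFeatureVector(uniq.astype(np.int64), cnt.astype(np.int64))
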