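"""MinHash genome sketches and Mash-style distances.

A sketch keeps the ``s`` smallest 64-bit hash values over the distinct
canonical k-mers of a genome (bottom-s MinHash).  The Jaccard index of two
genomes is estimated from the bottom-s values of the merged sketch, and
converted to an evolutionary distance with the Mash formula

    d = -(1/k) * ln(2j / (1 + j)),

clamped to [0, 1] (j = 0 maps to d = 1).  Defaults are k = 21 and
s = 10,000, the parameters commonly used for all-vs-all genome comparison;
tests and small studies may pass smaller ``s``.

Hashing: k-mers are 2-bit encoded (A=0, C=1, G=2, T=3), canonicalized as
min(code, revcomp code), and mixed with a seeded splitmix64 finalizer — a
well-mixed, non-cryptographic 64-bit hash that is bit-exact for a given
seed.  k-mers containing non-ACGT characters are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10_000

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class KmerSketch:
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted, strictly increasing uint64, len <= s

    def __post_init__(self):
        if self.hashes.size > 1 and not np.all(np.diff(self.hashes.view(np.uint64)) > 0):
            raise ValueError("sketch hashes must be strictly increasing")


@dataclass(frozen=True)
class PairDistance:
    jaccard: float
    distance: float


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64 finalizer over a uint64 array (vectorized)."""
    z = x.astype(np.uint64) + np.uint64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    z = z + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of all valid canonical k-mers of ``seq`` (with multiplicity)."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    valid = codes >= 0
    c = np.where(valid, codes, 0).astype(np.int64)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    fwd = sliding_window_view(c, k) @ weights
    rev = sliding_window_view(3 - c, k) @ weights[::-1]
    ok = sliding_window_view(valid, k).all(axis=1)
    return np.minimum(fwd, rev)[ok]


def canonical_kmer_set(contigs: list[str], k: int) -> np.ndarray:
    """Distinct canonical k-mer codes over a set of contigs (sorted)."""
    parts = [canonical_kmer_codes(s, k) for s in contigs]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def exact_jaccard(contigs_a: list[str], contigs_b: list[str], k: int = DEFAULT_K) -> float:
    """Exact Jaccard index of the full canonical k-mer sets of two genomes."""
    a = canonical_kmer_set(contigs_a, k)
    b = canonical_kmer_set(contigs_b, k)
    if a.size == 0 and b.size == 0:
        raise ValueError("both genomes have no valid k-mers")
    inter = np.intersect1d(a, b, assume_unique=True).size
    union = a.size + b.size - inter
    return inter / union


def build_sketch(
    contigs,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 42,
) -> KmerSketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers.

    ``contigs`` is a list of sequences or a GenomeBin.  Raises if no contig
    yields a valid k-mer.
    """
    if hasattr(contigs, "contigs"):
        contigs = contigs.contigs
    if not (11 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and in [11, 31]")
    if s < 1:
        raise ValueError("sketch size s must be >= 1")
    kmers = canonical_kmer_set(list(contigs), k)
    if kmers.size == 0:
        raise ValueError("no k-mers: all contigs shorter than k or non-ACGT")
    hashes = np.sort(_splitmix64(kmers.astype(np.uint64), hash_seed))
    return KmerSketch(k=k, s=s, hash_seed=hash_seed, hashes=hashes[:s])


def mash_distance(a: KmerSketch, b: KmerSketch) -> PairDistance:
    """Mash-style distance from the bottom-s union of two sketches."""
    if a.k != b.k:
        raise ValueError("sketches have different k")
    if a.hash_seed != b.hash_seed:
        raise ValueError("sketches have different hash seeds")
    s = min(a.s, b.s)
    merged = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(
        merged, np.intersect1d(a.hashes, b.hashes, assume_unique=True), assume_unique=True
    ).size
    j = shared / merged.size
    if j <= 0:
        return PairDistance(jaccard=0.0, distance=1.0)
    if j >= 1:
        return PairDistance(jaccard=1.0, distance=0.0)
    d = -np.log(2 * j / (1 + j)) / a.k
    return PairDistance(jaccard=j, distance=float(min(1.0, max(0.0, d))))


def distance_matrix(
    bins,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 42,
) -> tuple[list[str], np.ndarray]:
    """All-vs-all Mash distances; returns (bin ids, symmetric matrix, zero diagonal)."""
    if len(bins) < 2:
        raise ValueError("need >= 2 bins for a distance matrix")
    sketches = []
    ids = []
    for b in bins:
        try:
            sketches.append(build_sketch(b, k=k, s=s, hash_seed=hash_seed))
        except ValueError as e:
            raise ValueError(f"bin {getattr(b, 'bin_id', '?')}: {e}") from e
        ids.append(getattr(b, "bin_id", str(len(ids))))
    n = len(bins)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(sketches[i], sketches[j]).distance
            mat[i, j] = mat[j, i] = d
    return ids, mat
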