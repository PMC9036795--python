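"""MinHash genome sketches and Mash-style distances.

A sketch keeps the s smallest 64-bit hashes of the canonical k-mers of a
genome (canonical = lexicographic minimum of a k-mer and its reverse
complement, so a genome and its reverse complement sketch identically).
The Mash distance between two sketches is

    d = -ln(2j / (1 + j)) / k

with j the Jaccard index estimated on the bottom-s sketch of the merged hash
union; d = 0 for identical sketches and is capped at 1 when j = 0.

Hashing is a seeded splitmix64-style finalizer applied to the 2-bit packed
canonical k-mer codes (k <= 31), vectorised over numpy uint64 arrays.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of all valid k-mer windows (canonical form)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    valid = codes != 255
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    window_valid = np.ones(n, dtype=bool)
    c64 = codes.astype(np.uint64)
    comp = (np.uint64(3) - c64)
    for i in range(k):
        col = c64[i:i + n]
        fwd |= col << np.uint64(2 * (k - 1 - i))
        rev |= comp[i:i + n] << np.uint64(2 * i)
        window_valid &= valid[i:i + n]
    canon = np.minimum(fwd, rev)
    return canon[window_valid]


@dataclasses.dataclass
class KmerSketch:
    genome_id: str
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted ascending, distinct, len <= s


def sketch(sequences: dict[str, str] | list[str] | str, k: int = 21,
           s: int = 1000, hash_seed: int = 42,
           genome_id: str = "") -> KmerSketch:
    """Bottom-s MinHash sketch of a genome (one or several sequences)."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    if isinstance(sequences, str):
        seqs = [sequences]
    elif isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if any(len(seq) < k for seq in seqs):
        raise ValueError(f"sequence shorter than k={k}")
    seed_mix = _splitmix64(np.array([hash_seed], dtype=np.uint64))[0]
    all_hashes = []
    for seq in seqs:
        codes = _kmer_codes(seq, k)
        if len(codes):
            all_hashes.append(_splitmix64(codes ^ seed_mix))
    if not all_hashes:
        raise ValueError("no valid k-mers (all windows contain non-ACGT bases)")
    hashes = np.unique(np.concatenate(all_hashes))[:s]
    return KmerSketch(genome_id, k, s, hash_seed, hashes)


def mash_distance(a: KmerSketch, b: KmerSketch) -> float:
    """Mash distance between two sketches built with the same k and seed."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("mismatched hash seeds")
    union = np.union1d(a.hashes, b.hashes)
    s_eff = min(max(a.s, b.s), len(union))
    bottom = union[:s_eff]
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    shared = int(np.isin(bottom, inter, assume_unique=True).sum())
    j = shared / s_eff
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.k
    return float(min(d, 1.0))


def distance_matrix(sketches: list[KmerSketch]):
    """Symmetric Mash distance matrix over a list of sketches (pandas DataFrame)."""
    import pandas as pd

    labels = [sk.genome_id for sk in sketches]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mash_distance(sketches[i], sketches[j])
    return pd.DataFrame(D, index=labels, columns=labels)
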