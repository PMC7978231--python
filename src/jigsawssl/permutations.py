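"""Jigsaw permutation sets with maximal pairwise Hamming distance.

The jigsaw pretext task scrambles the tiles of an image according to one of
``P`` fixed permutations and asks the network to recover the permutation
index.  With a 3x3 grid there are 9! = 362880 possible tile orderings, far
too many classes to learn, so a small subset is selected greedily so that
the chosen permutations are as mutually dissimilar as possible in Hamming
distance.  Index 0 is always the identity ordering (the unscrambled image);
indices 1..P are the scrambled pseudo-labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PermutationSet",
    "hamming_distance",
    "count_possible_orderings",
    "generate_permutation_set",
    "load_permutation_set",
]

# Exhaustive candidate enumeration is used when n_tiles! is at most this;
# above it, each greedy round scores a seeded random sample of candidates.
_EXHAUSTIVE_LIMIT = 10_000
_SAMPLE_PER_ROUND = 100_000


def hamming_distance(p1, p2) -> int:
    """Number of positions at which two equal-length orderings differ."""
    a = np.asarray(p1)
    b = np.asarray(p2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"permutations must be 1-D and of equal length, got {a.shape} vs {b.shape}"
        )
    return int(np.count_nonzero(a != b))


def count_possible_orderings(n_tiles: int) -> int:
    """Total number of tile orderings for a grid with ``n_tiles`` cells (n!)."""
    if n_tiles < 1:
        raise ValueError(f"n_tiles must be >= 1, got {n_tiles}")
    return math.factorial(n_tiles)


@dataclass(frozen=True)
class PermutationSet:
    """An ordered set of tile permutations indexed by jigsaw pseudo-label.

    ``entries[0]`` is always the identity (the unscrambled image);
    ``entries[1:]`` are the P scrambled orderings.
    """

    n_tiles: int
    entries: tuple[tuple[int, ...], ...]
    seed: int
    min_pairwise_hamming: int = field(default=0)

    @property
    def P(self) -> int:
        return len(self.entries) - 1

    def __post_init__(self):
        ident = tuple(range(self.n_tiles))
        if self.entries[0] != ident:
            raise ValueError("entry 0 must be the identity permutation")
        for e in self.entries:
            if sorted(e) != list(range(self.n_tiles)):
                raise ValueError(f"{e} is not a permutation of 0..{self.n_tiles - 1}")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("permutation entries must be distinct")

    def recompute_min_hamming(self) -> int:
        """Minimum Hamming distance over all unordered pairs of scrambled entries."""
        scrambled = self.entries[1:]
        if len(scrambled) < 2:
            return 0
        return min(
            hamming_distance(a, b) for a, b in itertools.combinations(scrambled, 2)
        )

    def save(self, path) -> None:
        """Write the set as plain text: header line, then one entry per line."""
        lines = [f"{self.n_tiles} {self.P} {self.seed}"]
        lines += [" ".join(str(v) for v in e) for e in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


def load_permutation_set(path) -> PermutationSet:
    lines = Path(path).read_text().strip().splitlines()
    n_tiles, P, seed = (int(v) for v in lines[0].split())
    entries = tuple(tuple(int(v) for v in ln.split()) for ln in lines[1 : P + 2])
    pset = PermutationSet(n_tiles=n_tiles, entries=entries, seed=seed)
    return PermutationSet(
        n_tiles=n_tiles,
        entries=entries,
        seed=seed,
        min_pairwise_hamming=pset.recompute_min_hamming(),
    )


def _one_hot(perms: np.ndarray, n: int) -> np.ndarray:
    """Flattened one-hot encoding; Hamming distance becomes n - dot product."""
    return np.eye(n, dtype=np.float32)[perms].reshape(len(perms), n * n)


def generate_permutation_set(n_tiles: int, P: int, seed: int = 0) -> PermutationSet:
    """Greedily select ``P`` scrambled permutations maximising min Hamming distance.

    Starts from a uniformly random non-identity permutation, then repeatedly
    adds the candidate whose minimum Hamming distance to the already-selected
    entries is largest, breaking ties toward the lexicographically smallest
    candidate.  For small grids (n_tiles! <= 10000) every permutation is a
    candidate; for larger grids each round scores a seeded uniform sample of
    at most 100000 permutations.  Deterministic for a fixed seed.
    """
    if n_tiles < 2:
        raise ValueError(f"n_tiles must be >= 2, got {n_tiles}")
    n_total = count_possible_orderings(n_tiles)
    if not 1 <= P <= n_total - 1:
        raise ValueError(
            f"P must be in [1, {n_total - 1}] for n_tiles={n_tiles}, got {P}"
        )

    rng = np.random.default_rng(seed)
    identity = np.arange(n_tiles)
    exhaustive = n_total <= _EXHAUSTIVE_LIMIT

    if exhaustive:
        # itertools yields permutations in lexicographic order
        all_perms = np.array(
            [p for p in itertools.permutations(range(n_tiles))], dtype=np.int64
        )
        all_perms = all_perms[(all_perms != identity).any(axis=1)]
        first = all_perms[int(rng.integers(len(all_perms)))]
    else:
        first = rng.permutation(n_tiles)
        while (first == identity).all():
            first = rng.permutation(n_tiles)

    selected = np.array([first])
    while len(selected) < P:
        if exhaustive:
            candidates = all_perms
        else:
            sample = rng.permuted(
                np.tile(np.arange(n_tiles), (_SAMPLE_PER_ROUND, 1)), axis=1
            )
            # dedupe + lex-sort via the base-n positional key (bijective)
            key = sample @ (n_tiles ** np.arange(n_tiles - 1, -1, -1))
            order = np.argsort(key, kind="stable")
            sample, key = sample[order], key[order]
            keep = np.empty(len(sample), dtype=bool)
            keep[0] = True
            keep[1:] = key[1:] != key[:-1]
            candidates = sample[keep]
            candidates = candidates[(candidates != identity).any(axis=1)]
        # min Hamming distance of each candidate to the selected set via
        # one-hot dot products (distance = n - matches).  Already-selected
        # candidates score 0 so they are never re-picked; argmax takes the
        # first (lexicographically smallest) maximiser.
        matches = _one_hot(candidates, n_tiles) @ _one_hot(selected, n_tiles).T
        dists = n_tiles - matches.max(axis=1)
        best = candidates[int(np.argmax(dists))]
        selected = np.vstack([selected, best[None, :]])

    entries = (tuple(range(n_tiles)), *(tuple(int(v) for v in row) for row in selected))
    pset = PermutationSet(n_tiles=n_tiles, entries=entries, seed=seed)
    return PermutationSet(
        n_tiles=n_tiles,
        entries=entries,
        seed=seed,
        min_pairwise_hamming=pset.recompute_min_hamming(),
    )
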