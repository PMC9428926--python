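"""Design and verification of error-detecting / error-correcting DNA barcodes.

Barcodes whose minimum pairwise Hamming distance is >= 2 can detect a single
substitution sequencing error (the corrupted word is no longer a member of the
set); distance >= 3 additionally allows correction by nearest-codeword
decoding.  This module enumerates candidate barcodes, measures set distances,
and constructs maximum- (exact) or maximal- (greedy) cardinality sets at a
requested minimum distance.

The exact search is a maximum-clique branch-and-bound on the graph whose
vertices are candidate barcodes and whose edges join pairs at distance
>= min_d, with a greedy-colouring upper bound and, when searching the full
4^length pool, translation symmetry-breaking (codes are invariant under
position-wise alphabet translation, so the all-A word may be assumed to be a
member).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Set, Tuple

__all__ = [
    "BarcodeSet",
    "hamming",
    "enumerate_barcodes",
    "verify_set",
    "max_distance_set",
    "nearest_codeword",
    "DEFAULT_DETECTING_24",
]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class BarcodeSet:
    """A named set of equal-length DNA barcodes with its computed minimum
    pairwise Hamming distance and the corresponding capability label."""

    length: int
    members: frozenset
    min_distance: int
    label: str  # plain | detecting | correcting

    def __post_init__(self) -> None:
        for m in self.members:
            if len(m) != self.length:
                raise ValueError(f"barcode {m!r} is not length {self.length}")

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> List[str]:
        return sorted(self.members)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length DNA strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def enumerate_barcodes(length: int) -> List[str]:
    """All 4**length DNA strings of the given length, lexicographic."""
    if not 1 <= length <= 8:
        raise ValueError("barcode length must be between 1 and 8")
    return ["".join(p) for p in product(_ALPHABET, repeat=length)]


def _label(min_distance: int) -> str:
    if min_distance >= 3:
        return "correcting"
    if min_distance >= 2:
        return "detecting"
    return "plain"


def verify_set(members: Sequence[str]) -> Tuple[int, str]:
    """Minimum pairwise Hamming distance of a barcode list and its label.

    A singleton set has no pairs; its distance is reported as the barcode
    length (vacuously correcting).
    """
    members = list(members)
    if not members:
        raise ValueError("empty barcode set")
    length = len(members[0])
    if any(len(m) != length for m in members):
        raise ValueError("barcodes have unequal lengths")
    if len(set(members)) != len(members):
        return 0, _label(0)
    if len(members) == 1:
        return length, _label(length)
    min_d = min(
        hamming(members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    )
    return min_d, _label(min_d)


def make_barcode_set(members: Sequence[str]) -> BarcodeSet:
    min_d, label = verify_set(members)
    return BarcodeSet(
        length=len(next(iter(members))),
        members=frozenset(members),
        min_distance=min_d,
        label=label,
    )


def nearest_codeword(word: str, members: Sequence[str],
                     max_distance: int = 1) -> Optional[str]:
    """Unique nearest codeword within ``max_distance`` of ``word``, or None
    when no codeword (or more than one at the minimum distance) qualifies."""
    best_d = max_distance + 1
    best: Optional[str] = None
    tied = False
    for m in members:
        d = hamming(word, m)
        if d < best_d:
            best_d, best, tied = d, m, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None
    return best


# ---------------------------------------------------------------------------
# Maximum / maximal distance-d sets
# ---------------------------------------------------------------------------

def _greedy_code(pool: Sequence[str], min_d: int) -> List[str]:
    """Lexicographic first-fit: scan the pool in order, keep every barcode at
    distance >= min_d from all kept ones.  The result is subset-maximal."""
    kept: List[str] = []
    for cand in pool:
        if all(hamming(cand, k) >= min_d for k in kept):
            kept.append(cand)
    return kept


def _max_clique(adj: List[int], order: Sequence[int],
                initial: Sequence[int] = ()) -> List[int]:
    """Maximum clique via branch-and-bound with a greedy-colouring bound.

    ``adj[v]`` is a bitmask of the neighbours of vertex v; ``initial`` seeds
    the incumbent (e.g. a greedy clique) so pruning starts tight.  Returns
    vertex indices of one maximum clique (deterministic for a fixed order).
    """
    best: List[int] = list(initial)

    def colour_sort(cand: int) -> List[Tuple[int, int]]:
        # Greedy colouring: vertices grouped into independent classes; a
        # vertex with colour c can extend a clique by at most c vertices.
        classes: List[int] = []
        coloured: List[Tuple[int, int]] = []
        v = cand
        while v:
            low = v & -v
            idx = low.bit_length() - 1
            a = adj[idx]
            for ci, cls in enumerate(classes):
                if not (a & cls):
                    classes[ci] = cls | low
                    coloured.append((idx, ci + 1))
                    break
            else:
                classes.append(low)
                coloured.append((idx, len(classes)))
            v ^= low
        # Emit class-by-class: the early return in expand() requires that
        # everything after a vertex has colour <= that vertex's colour.
        coloured.sort(key=lambda t: t[1])
        return coloured

    def expand(clique: List[int], cand: int) -> None:
        nonlocal best
        coloured = colour_sort(cand)
        # Process highest colour first so the bound prunes early.
        for v, c in reversed(coloured):
            if len(clique) + c <= len(best):
                return
            clique.append(v)
            nxt = cand & adj[v]
            if nxt:
                expand(clique, nxt)
            elif len(clique) > len(best):
                best = clique.copy()
            clique.pop()
            cand &= ~(1 << v)

    full = 0
    for v in order:
        full |= 1 << v
    expand([], full)
    return best


def max_distance_set(
    length: int,
    min_d: int,
    mode: str = "exact",
    candidate_pool: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> BarcodeSet:
    """Construct a barcode set with minimum pairwise distance >= ``min_d``.

    mode 'exact' returns a maximum-cardinality set (branch-and-bound clique
    search over the distance graph; limited to pools of <= 256 candidates).
    mode 'greedy' returns a maximal set by lexicographic first-fit over the
    pool ordering; both modes are deterministic.  ``candidate_pool`` restricts
    the search, e.g. to integration-competent barcodes; ``seed`` shuffles the
    greedy pool ordering when given (exact mode ignores it).
    """
    if min_d > length:
        raise ValueError(f"min_d {min_d} exceeds barcode length {length}")
    if min_d < 1:
        raise ValueError("min_d must be >= 1")
    if candidate_pool is None:
        pool = enumerate_barcodes(length)
        full_pool = True
    else:
        pool = list(dict.fromkeys(candidate_pool))  # dedupe, keep order
        if any(len(p) != length for p in pool):
            raise ValueError("candidate pool has barcodes of the wrong length")
        full_pool = False

    if mode == "greedy":
        if seed is not None:
            import random

            rng = random.Random(seed)
            pool = pool.copy()
            rng.shuffle(pool)
        return make_barcode_set(_greedy_code(pool, min_d))

    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if len(pool) > 256:
        raise ValueError("exact mode is limited to pools of <= 256 candidates")

    if full_pool:
        # Translation symmetry: mapping each base b -> translate(b - w[i]) at
        # every position i sends any code to a code of equal size containing
        # A^length, so the all-A word can be fixed as the first codeword.
        anchor = "A" * length
        search = [b for b in pool if hamming(b, anchor) >= min_d]
    else:
        anchor = None
        search = pool
    adj, order = _distance_graph(search, min_d)
    vert = {b: i for i, b in enumerate(search)}
    seed = [vert[b] for b in _greedy_code(search, min_d)]
    clique = _max_clique(adj, order, initial=seed)
    members = [search[v] for v in clique]
    if anchor is not None:
        members.append(anchor)
    return make_barcode_set(members)


def _distance_graph(pool: Sequence[str], min_d: int) -> Tuple[List[int], List[int]]:
    n = len(pool)
    adj = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if hamming(pool[i], pool[j]) >= min_d:
                adj[i] |= 1 << j
                adj[j] |= 1 << i
    # Degeneracy-flavoured static order: descending degree, index tie-break.
    order = sorted(range(n), key=lambda v: (-adj[v].bit_count(), v))
    return adj, order


def _default_detecting_pool() -> List[str]:
    # Integration-preference pool: thymine at the third barcode position
    # (0-based index 2) is strongly disfavoured for transposition, so the
    # shipped default avoids it.  This is the package's own default set, not
    # a reproduction of any published membership list.
    return [b for b in enumerate_barcodes(4) if b[2] != "T"]


def _build_default_24() -> BarcodeSet:
    kept = _greedy_code(_default_detecting_pool(), 2)[:24]
    return make_barcode_set(kept)


#: Shipped default: 24 length-4 error-detecting barcodes (min distance >= 2),
#: drawn deterministically from a pool avoiding T at position 2 (0-based).
DEFAULT_DETECTING_24: BarcodeSet = _build_default_24()
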