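"""Constrained codeword enumeration and adaptive codebook selection.

The codec maps fixed-length binary strings (``l0`` bits) to fixed-length DNA
codewords (``li`` nt) that individually satisfy the biological constraints.
Two problems are solved here:

1. *Which DNA words of length N are usable?* — a depth-first enumeration of
   the 4-ary tree of length-N words, pruned exactly: a prefix is abandoned as
   soon as its homopolymer run exceeds the cap or its GC count can no longer
   reach the admissible window. An exact dynamic-programming count over
   (GC count, last base, run length) states gives codeword supply without
   materializing words, which matters for long codewords.

2. *Which (l0, li) pair stores the most bits per nucleotide for this file?* —
   the bit stream is scanned block-wise at every candidate l0; the number of
   distinct l0-bit strings q determines the shortest feasible codeword length
   li, and the theoretical storage density

       D = L0 / (L' + Lc)      [bits/nt]

   with L' = (L*/l0)·li the emitted payload length and Lc = q·(l0+li) the
   codebook's own footprint, is maximized over the scan range. Ties prefer
   smaller l0, then smaller li, so selection is deterministic.

Codewords are uniform-length per codebook, which makes decoding a trivial
fixed-width inverse lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np

from .constraints import ConstraintParams, passes_biological_constraints

BASES = ("A", "C", "G", "T")  # lexicographic order
_GC = {"A": 0, "C": 1, "G": 1, "T": 0}
_EPS = 1e-9

MAX_CODEWORD_LEN = 16
MAX_BRUTE_FORCE_LEN = 8


def _gc_count_bounds(n: int, params: ConstraintParams) -> tuple[int, int]:
    """Smallest and largest admissible GC counts for a length-*n* word."""
    lo = int(np.ceil(params.gc_min * n - _EPS))
    hi = int(np.floor(params.gc_max * n + _EPS))
    return max(lo, 0), min(hi, n)


@lru_cache(maxsize=None)
def count_codewords(n: int, params: ConstraintParams = ConstraintParams()) -> int:
    """Exact number of length-*n* words satisfying the constraints.

    Dynamic program over (GC count, last base, current run length); exact for
    any *n*, O(n^2) states.
    """
    if n < 1:
        return 0
    lo, hi = _gc_count_bounds(n, params)
    if lo > hi:
        return 0
    # state: (gc_count, base_index, run_length) -> number of words
    states: dict[tuple[int, int, int], int] = {}
    for b, base in enumerate(BASES):
        states[(_GC[base], b, 1)] = states.get((_GC[base], b, 1), 0) + 1
    for pos in range(1, n):
        nxt: dict[tuple[int, int, int], int] = {}
        remaining = n - pos - 1
        for (g, b, run), cnt in states.items():
            for nb, nbase in enumerate(BASES):
                nrun = run + 1 if nb == b else 1
                if nrun > params.max_homopolymer:
                    continue
                ng = g + _GC[nbase]
                if ng > hi or ng + remaining < lo:
                    continue
                key = (ng, nb, nrun)
                nxt[key] = nxt.get(key, 0) + cnt
        states = nxt
    return sum(cnt for (g, _, _), cnt in states.items() if lo <= g <= hi)


def iter_codewords(
    n: int, params: ConstraintParams = ConstraintParams()
) -> Iterator[str]:
    """Lazily yield valid length-*n* codewords in lexicographic order.

    The depth-first search prunes a prefix when its homopolymer run exceeds
    the cap, its GC count exceeds the window ceiling, or the remaining
    positions cannot lift the GC count to the window floor. Pruning is exact:
    no valid word is lost (checked against brute force in the test suite).
    """
    if n < 1:
        return
    lo, hi = _gc_count_bounds(n, params)
    if lo > hi:
        return

    prefix = [""] * n

    def descend(pos: int, gc: int, last: str, run: int) -> Iterator[str]:
        if pos == n:
            yield "".join(prefix)
            return
        remaining = n - pos - 1
        for base in BASES:
            nrun = run + 1 if base == last else 1
            if nrun > params.max_homopolymer:
                continue
            ng = gc + _GC[base]
            if ng > hi or ng + remaining < lo:
                continue
            prefix[pos] = base
            yield from descend(pos + 1, ng, base, nrun)

    yield from descend(0, 0, "", 0)


@dataclass
class CodewordSet:
    """All constraint-satisfying codewords of one length, sorted lexicographically."""

    length: int
    codewords: list[str]

    def __len__(self) -> int:
        return len(self.codewords)


def enumerate_codewords(
    n: int, params: ConstraintParams = ConstraintParams()
) -> CodewordSet:
    """Materialize the pruned enumeration for 1 <= n <= 16."""
    if not 1 <= n <= MAX_CODEWORD_LEN:
        raise ValueError(f"codeword length must be in [1, {MAX_CODEWORD_LEN}], got {n}")
    return CodewordSet(n, list(iter_codewords(n, params)))


def brute_force_codewords(
    n: int, params: ConstraintParams = ConstraintParams()
) -> CodewordSet:
    """Filter all 4^n words by the constraint predicate. Test oracle; n <= 8."""
    if n > MAX_BRUTE_FORCE_LEN:
        raise ValueError(f"brute force capped at n <= {MAX_BRUTE_FORCE_LEN}")
    if n < 1:
        raise ValueError("n must be >= 1")
    words = [""]
    for _ in range(n):
        words = [w + b for w in words for b in BASES]
    return CodewordSet(
        n, [w for w in words if passes_biological_constraints(w, params)]
    )


# ---------------------------------------------------------------------------
# bit-stream scanning
# ---------------------------------------------------------------------------


def _bits_array(bits: str) -> np.ndarray:
    arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    if arr.size and arr.max() > 1:
        raise ValueError("bit stream must contain only '0' and '1'")
    return arr


def pad_stream(bits: str, l0: int) -> str:
    """Append '0' bits until the length is a multiple of *l0*."""
    if l0 < 1:
        raise ValueError("l0 must be >= 1")
    rem = len(bits) % l0
    return bits if rem == 0 else bits + "0" * (l0 - rem)


def _block_counts(bits: str, l0: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct l0-bit block values and their counts (length must divide)."""
    if len(bits) % l0 != 0:
        raise ValueError("stream length must be a multiple of l0; pad first")
    arr = _bits_array(bits)
    if arr.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mat = arr.reshape(-1, l0).astype(np.int64)
    weights = (1 << np.arange(l0 - 1, -1, -1)).astype(np.int64)
    values = mat @ weights
    return np.unique(values, return_counts=True)


@dataclass
class FrequencyTable:
    """Empirical distribution of l0-bit strings in a padded stream.

    Entries are (bitstring, count, probability), sorted by probability
    descending with ties broken by bitstring ascending.
    """

    l0: int
    entries: list[tuple[str, int, float]]

    def __post_init__(self) -> None:
        total = sum(p for _, _, p in self.entries)
        if self.entries and abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, expected 1")
        if any(c <= 0 for _, c, _ in self.entries):
            raise ValueError("counts must be positive")

    @property
    def q(self) -> int:
        return len(self.entries)

    @property
    def total_blocks(self) -> int:
        return sum(c for _, c, _ in self.entries)

    def strings(self) -> list[str]:
        return [s for s, _, _ in self.entries]

    def probabilities(self) -> list[float]:
        return [p for _, _, p in self.entries]


def scan_frequencies(padded_bits: str, l0: int) -> FrequencyTable:
    """Count non-overlapping consecutive l0-bit blocks of a padded stream."""
    values, counts = _block_counts(padded_bits, l0)
    n_blocks = int(counts.sum())
    entries = [
        (format(int(v), f"0{l0}b"), int(c), int(c) / n_blocks)
        for v, c in zip(values, counts)
    ]
    entries.sort(key=lambda e: (-e[2], e[0]))
    return FrequencyTable(l0, entries)


def average_code_length(table: FrequencyTable, lengths: list[int]) -> float:
    """Probability-weighted mean codeword length over the table's strings."""
    if len(lengths) != table.q:
        raise ValueError(
            f"{len(lengths)} lengths supplied for {table.q} table entries"
        )
    return float(sum(p * l for (_, _, p), l in zip(table.entries, lengths)))


def match_codeword_length(
    q: int, params: ConstraintParams = ConstraintParams(), max_len: int = MAX_CODEWORD_LEN
) -> int:
    """Smallest codeword length whose constrained supply covers *q* strings."""
    if q < 1:
        raise ValueError("q must be >= 1")
    for li in range(1, max_len + 1):
        if count_codewords(li, params) >= q:
            return li
    raise ValueError(
        f"no codeword length <= {max_len} offers {q} constraint-satisfying words"
    )


@dataclass
class DensityRecord:
    """One evaluated (l0, li) configuration and its theoretical density."""

    l0: int
    li: int
    stream_bits: int  # L0, original stream length in bits
    padded_bits: int  # L*, after padding to a multiple of l0
    avg_code_length: float  # L, probability-weighted codeword length (= li here)
    payload_nt: float  # L', emitted DNA length in nt
    codebook_nt: float  # Lc, codebook footprint: q·(l0 + li)
    density: float  # D = L0 / (L' + Lc), bits per nt


def storage_density(
    l0: int, li: int, stream_bits: int, table: FrequencyTable
) -> DensityRecord:
    """Theoretical storage density of one (l0, li) configuration.

    With uniform codeword length the payload is L' = (L*/l0)·li nt; the
    codebook adds Lc = q·(l0 + li) (one unit per stored bit plus one per
    stored nucleotide). Density is stream bits per total nucleotide,
    D = L0 / (L' + Lc).
    """
    n_blocks = table.total_blocks
    padded = n_blocks * l0
    payload = n_blocks * float(li)
    codebook_nt = float(table.q * (l0 + li))
    density = stream_bits / (payload + codebook_nt)
    return DensityRecord(
        l0=l0,
        li=li,
        stream_bits=stream_bits,
        padded_bits=padded,
        avg_code_length=float(li),
        payload_nt=payload,
        codebook_nt=codebook_nt,
        density=density,
    )


@dataclass
class Codebook:
    """Bijection between l0-bit strings and li-nt codewords."""

    l0: int
    li: int
    forward: dict[str, str]  # bitstring -> codeword
    inverse: dict[str, str]  # codeword -> bitstring

    @classmethod
    def from_forward(cls, l0: int, li: int, forward: dict[str, str]) -> "Codebook":
        inverse = {cw: s for s, cw in forward.items()}
        if len(inverse) != len(forward):
            raise ValueError("codeword assignment is not injective")
        return cls(l0, li, dict(forward), inverse)

    @property
    def q(self) -> int:
        return len(self.forward)


def initial_codebook(
    table: FrequencyTable, li: int, params: ConstraintParams = ConstraintParams()
) -> Codebook:
    """Pre-optimization mapping: strings by descending probability onto
    codewords in lexicographic order."""
    strings = table.strings()  # already probability-desc, bitstring-asc
    gen = iter_codewords(li, params)
    forward: dict[str, str] = {}
    for s in strings:
        try:
            forward[s] = next(gen)
        except StopIteration:
            raise ValueError(
                f"codeword supply at length {li} exhausted after "
                f"{len(forward)} of {table.q} strings"
            ) from None
    return Codebook.from_forward(table.l0, li, forward)


def select_codebook_params(
    bits: str,
    params: ConstraintParams = ConstraintParams(),
    scan_min: int = 3,
    scan_max: int = 30,
) -> tuple[DensityRecord, Codebook, FrequencyTable]:
    """Pick the (l0, li) configuration with maximal theoretical density.

    Every l0 in [scan_min, scan_max] is evaluated (skipping those whose
    distinct-string count exceeds the codeword supply at the length cap);
    the argmax density wins, ties broken by smaller l0 then smaller li.
    Returns the winning record, the initial (pre-optimization) codebook, and
    the frequency table of the winning scan length.
    """
    if not bits:
        raise ValueError("cannot select codebook parameters for an empty stream")
    if not 1 <= scan_min <= scan_max:
        raise ValueError("require 1 <= scan_min <= scan_max")
    stream_bits = len(bits)
    best: DensityRecord | None = None
    for l0 in range(scan_min, scan_max + 1):
        padded = pad_stream(bits, l0)
        _, counts = _block_counts(padded, l0)
        q = int(counts.size)
        try:
            li = match_codeword_length(q, params)
        except ValueError:
            continue  # q exceeds supply at the length cap
        n_blocks = int(counts.sum())
        payload = n_blocks * float(li)
        codebook_nt = float(q * (l0 + li))
        density = stream_bits / (payload + codebook_nt)
        rec = DensityRecord(
            l0=l0,
            li=li,
            stream_bits=stream_bits,
            padded_bits=n_blocks * l0,
            avg_code_length=float(li),
            payload_nt=payload,
            codebook_nt=codebook_nt,
            density=density,
        )
        if (
            best is None
            or rec.density > best.density + _EPS
            or (
                abs(rec.density - best.density) <= _EPS
                and (rec.l0, rec.li) < (best.l0, best.li)
            )
        ):
            best = rec
    if best is None:
        raise ValueError("no feasible (l0, li) configuration in the scan range")
    table = scan_frequencies(pad_stream(bits, best.l0), best.l0)
    return best, initial_codebook(table, best.li, params), table
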