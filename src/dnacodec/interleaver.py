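"""Adaptive four-block interleaver with cyclic risk-driven correction.

A payload that still violates a constraint after encoding (a primer 3′ k-mer
formed across codeword junctions, or a homopolymer run spanning codewords) is
repaired by *rearranging* its content with a bijective permutation: base
counts — hence GC content — are exactly preserved, only positions change.

The permutation adapts to the payload. The sequence is split into ``cells``
of ``unit_nt`` bases (1 by default; the codec passes the codeword length when
it divides the payload, so rearrangement respects codeword boundaries and
cannot break the per-codeword run and GC guarantees). Cells are written
row-major into an N×M grid with N·M = cells (+ minimal filler when the cell
count has no suitable factorization), N ≠ M and |N − M| minimal, N ≥ M. The
grid splits into four sub-blocks at row n1 and column m1, where n1 + n2 = N
and m1 + m2 = M are the most balanced *unequal* splits (larger part first; an
even side X splits as (X/2+1, X/2−1), so a side of 2 yields an empty part).
Each sub-block is scrambled by its own fixed bijection:

* top-left  (rows < n1, cols < m1): column-major read, rewritten row-major;
* top-right (rows < n1, cols >= m1): rotated 180°;
* bottom-left (rows >= n1, cols < m1): boustrophedon (snake) read;
* bottom-right (rows >= n1, cols >= m1): reversed column-major read.

Correction applies this permutation repeatedly (permutation powers), testing
the risk predicate after each pass, and keeps the first risk-free
arrangement; if the iteration cap is reached, the least risky arrangement
seen is emitted and flagged as residual risk rather than dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .constraints import (
    ConstraintParams,
    PrimerLibrary,
    find_nonspecific_sites,
    gc_content,
    normalize_sequence,
)

MIN_CELLS = 6  # below this no four-block split is meaningful
_FILLER = "ATGC"  # cycled filler: ~50% GC, never forms a homopolymer


@dataclass(frozen=True)
class InterleaverPlan:
    """Grid geometry and iteration count; sufficient to invert the permutation."""

    length: int  # L, payload length in nt before filler
    pad_nt: int  # filler bases appended to reach n_rows * n_cols cells
    unit_nt: int  # bases per grid cell (codeword-aligned when > 1)
    n_rows: int  # N
    n_cols: int  # M
    n1: int
    n2: int
    m1: int
    m2: int
    iterations: int = 0

    # derived sub-block sides (top-right is n1 x m2, bottom-left n2 x m1)
    @property
    def n3(self) -> int:
        return self.n1

    @property
    def n4(self) -> int:
        return self.n2

    @property
    def m3(self) -> int:
        return self.m2

    @property
    def m4(self) -> int:
        return self.m1

    @property
    def grid_nt(self) -> int:
        return self.n_rows * self.n_cols * self.unit_nt


def _best_factor_pair(total: int) -> tuple[int, int] | None:
    """Factor pair (N, M), N >= M >= 2, N != M, minimizing N - M; None if none."""
    best: tuple[int, int] | None = None
    for m in range(2, int(np.sqrt(total)) + 1):
        if total % m:
            continue
        n = total // m
        if n == m:
            continue
        if best is None or n - m < best[0] - best[1]:
            best = (n, m)
    return best


def _unequal_split(side: int) -> tuple[int, int]:
    """Most balanced (a, b), a + b = side, a > b, a != b; b may be 0 for side=2."""
    if side % 2:
        return (side + 1) // 2, side // 2
    return side // 2 + 1, side // 2 - 1


def plan_interleaver(length: int, unit_nt: int = 1) -> InterleaverPlan:
    """Choose grid and sub-block geometry for a payload of *length* nt.

    The payload is treated as length/unit_nt cells; the smallest pad >= 0 (in
    whole cells) making a valid factor pair exist is used, and among
    factorizations the pair closest to square (but not square) wins.
    """
    if unit_nt < 1 or length % unit_nt:
        raise ValueError(f"unit_nt {unit_nt} must divide the length {length}")
    cells = length // unit_nt
    if cells < MIN_CELLS:
        raise ValueError(
            f"interleaver needs at least {MIN_CELLS} cells, got {cells} "
            f"({length} nt / unit {unit_nt})"
        )
    for pad_cells in itertools.count(0):
        pair = _best_factor_pair(cells + pad_cells)
        if pair is not None:
            n, m = pair
            n1, n2 = _unequal_split(n)
            m1, m2 = _unequal_split(m)
            return InterleaverPlan(
                length=length, pad_nt=pad_cells * unit_nt, unit_nt=unit_nt,
                n_rows=n, n_cols=m, n1=n1, n2=n2, m1=m1, m2=m2,
            )
    raise AssertionError("unreachable")


def permutation(plan: InterleaverPlan) -> np.ndarray:
    """Base-level source-index array: output position i takes base perm[i]."""
    n, m, n1, m1 = plan.n_rows, plan.n_cols, plan.n1, plan.m1
    idx = np.arange(n * m).reshape(n, m)
    out = idx.copy()

    block = idx[:n1, :m1]  # column-major read, row-major rewrite
    out[:n1, :m1] = block.flatten(order="F").reshape(block.shape)

    block = idx[:n1, m1:]  # 180 degree rotation
    out[:n1, m1:] = block[::-1, ::-1]

    block = idx[n1:, :m1].copy()  # snake read
    block[1::2] = block[1::2, ::-1]
    out[n1:, :m1] = block

    block = idx[n1:, m1:]  # reversed column-major read
    out[n1:, m1:] = block.flatten(order="F")[::-1].reshape(block.shape)

    cell_perm = out.ravel()
    if plan.unit_nt == 1:
        return cell_perm
    u = plan.unit_nt
    return (cell_perm[:, None] * u + np.arange(u)).ravel()


def _filler(pad: int) -> str:
    return (_FILLER * (pad // 4 + 1))[:pad]


def _apply(seq: str, perm: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr[perm].tobytes().decode("ascii")


def interleave(seq: str, plan: InterleaverPlan) -> str:
    """One forward pass. Accepts the bare payload (length L, filler appended
    here) or an already padded arrangement (full grid length)."""
    s = normalize_sequence(seq)
    if len(s) == plan.length:
        s += _filler(plan.pad_nt)
    if len(s) != plan.grid_nt:
        raise ValueError(
            f"sequence length {len(seq)} matches neither L={plan.length} "
            f"nor grid size {plan.grid_nt}"
        )
    return _apply(s, permutation(plan))


def deinterleave(seq: str, plan: InterleaverPlan, iterations: int | None = None) -> str:
    """Invert *iterations* forward passes (default: plan.iterations) and strip filler."""
    s = normalize_sequence(seq)
    k = plan.iterations if iterations is None else iterations
    if k < 0:
        raise ValueError("iterations must be >= 0")
    if k == 0:
        if len(s) == plan.length:
            return s
        if len(s) != plan.grid_nt:
            raise ValueError("length matches neither L nor grid size")
        return s[: plan.length]
    if len(s) != plan.grid_nt:
        raise ValueError(
            f"interleaved sequence must have grid length {plan.grid_nt}, "
            f"got {len(s)}"
        )
    inverse = np.argsort(permutation(plan), kind="stable")
    for _ in range(k):
        s = _apply(s, inverse)
    return s[: plan.length]


def _homopolymer_violations(seq: str, cap: int) -> int:
    """Number of maximal runs longer than *cap*."""
    count = run = 0
    prev = ""
    for base in seq + "$":  # sentinel flushes the final run
        if base == prev:
            run += 1
        else:
            if run > cap:
                count += 1
            run = 1
        prev = base
    return count


def _risk_score(
    seq: str, lib: PrimerLibrary, params: ConstraintParams
) -> tuple[int, int]:
    return (
        len(find_nonspecific_sites(seq, lib, params)),
        _homopolymer_violations(seq, params.max_homopolymer),
    )


def correct_sequence(
    seq: str,
    lib: PrimerLibrary,
    params: ConstraintParams = ConstraintParams(),
    max_iters: int = 16,
    unit_nt: int = 1,
) -> tuple[str, InterleaverPlan | None, bool]:
    """Cyclic interleaving calibration of one payload.

    Returns ``(sequence, plan, residual_risk)``. A payload already risk-free
    is returned unchanged with plan ``None`` (zero iterations). Otherwise the
    plan's permutation is applied repeatedly, re-testing after each pass; the
    first risk-free arrangement wins. If *max_iters* passes never clear the
    risk — or the payload is too short to grid — the least risky arrangement
    seen (fewest nonspecific sites, then fewest homopolymer violations, then
    earliest pass) is returned flagged.

    ``unit_nt`` > 1 restricts the rearrangement to codeword-aligned cells, so
    per-codeword run and GC guarantees survive the permutation.

    GC content can never be repaired here — base counts are conserved — but
    codeword-level GC guarantees make payload GC violations structurally
    impossible; the flag covers forced fixtures and violations that every
    tested arrangement retains.
    """
    s = normalize_sequence(seq)
    score = _risk_score(s, lib, params)
    gc_ok = params.gc_min <= gc_content(s) <= params.gc_max
    if score == (0, 0) and gc_ok:
        return s, None, False
    try:
        plan = plan_interleaver(len(s), unit_nt)
    except ValueError:
        return s, None, True  # too short to grid; emit flagged
    perm = permutation(plan)
    current = s + _filler(plan.pad_nt)
    best: tuple[tuple[int, int], int, str] | None = None
    for k in range(1, max_iters + 1):
        current = _apply(current, perm)
        score = _risk_score(current, lib, params)
        gc_now = params.gc_min <= gc_content(current) <= params.gc_max
        if score == (0, 0) and gc_now:
            return current, replace(plan, iterations=k), False
        if best is None or score < best[0]:
            best = (score, k, current)
    assert best is not None
    _, k, arrangement = best
    return arrangement, replace(plan, iterations=k), True
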