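"""Primer-aware codeword weighting and codebook optimization.

The initial codebook maps frequent strings to arbitrary (lexicographically
first) codewords. To suppress nonspecific pairing, codewords are weighted by
how often they occur as windows of the primers' 3′ regions: a sliding scan of
length li (stride 1) runs across the last ``region_nt`` bases (default 8, the
nonspecific k-mer length) of every primer, and each window equal to a valid
codeword increments that codeword's weight. The optimized mapping then sends
the most frequent strings to the *lightest* codewords, so base combinations
that appear near primer 3′ ends are used as rarely as possible in payloads.

Weights are counted on the primers as written (direct orientation) by
default; reverse-complement windows can be included explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .codebook import Codebook, CodewordSet, FrequencyTable, count_codewords, iter_codewords
from .constraints import ConstraintParams, PrimerLibrary, reverse_complement


@dataclass
class WeightedCodeword:
    """A codeword and its occurrence count across primer 3′-region windows."""

    codeword: str
    weight: int


def _primer_windows(
    lib: PrimerLibrary,
    li: int,
    region_nt: int = 8,
    include_reverse_complement: bool = False,
) -> Counter[str]:
    """Multiset of li-nt sliding windows over each primer's 3′ region.

    The region is the primer's last ``region_nt`` bases when li <= region_nt;
    for longer codewords a single window of the last li bases is used, which
    keeps the 3′-end focus without weighting interior primer content.
    """
    if li < 1:
        raise ValueError("codeword length must be >= 1")
    windows: Counter[str] = Counter()
    for _, seq in lib:
        region = seq[-region_nt:] if li <= region_nt else seq[-li:]
        for start in range(len(region) - li + 1):
            windows[region[start : start + li]] += 1
        if include_reverse_complement:
            rc = reverse_complement(region)
            for start in range(len(rc) - li + 1):
                windows[rc[start : start + li]] += 1
    return windows


def weight_codewords(
    cwset: CodewordSet,
    lib: PrimerLibrary,
    li: int | None = None,
    region_nt: int = 8,
    include_reverse_complement: bool = False,
) -> list[WeightedCodeword]:
    """Path weight of every codeword in *cwset* against the primer library.

    Windows that match no codeword in the set are discarded; codewords never
    observed keep weight 0. Output order follows the codeword set
    (lexicographic), so results are deterministic.
    """
    li = cwset.length if li is None else li
    if li != cwset.length:
        raise ValueError("li disagrees with the codeword set length")
    windows = _primer_windows(lib, li, region_nt, include_reverse_complement)
    return [WeightedCodeword(cw, windows.get(cw, 0)) for cw in cwset.codewords]


def _assign(
    table: FrequencyTable, ranked_codewords: list[str], li: int
) -> Codebook:
    strings = table.strings()  # probability desc, bitstring asc
    if len(ranked_codewords) < table.q:
        raise ValueError(
            f"only {len(ranked_codewords)} codewords available for "
            f"{table.q} strings"
        )
    forward = dict(zip(strings, ranked_codewords))
    return Codebook.from_forward(table.l0, li, forward)


def optimize_codebook(
    initial: Codebook,
    table: FrequencyTable,
    weights: list[WeightedCodeword],
) -> Codebook:
    """Reassign strings to codewords by ascending path weight.

    The i-th most frequent string receives the i-th lightest codeword; weight
    ties break lexicographically by codeword, probability ties by bitstring.
    The l0/li geometry of the initial codebook is preserved.
    """
    if table.l0 != initial.l0:
        raise ValueError("frequency table and codebook disagree on l0")
    seen = set()
    ranked = []
    for wc in sorted(weights, key=lambda w: (w.weight, w.codeword)):
        if wc.codeword in seen:
            raise ValueError(f"duplicate codeword in weights: {wc.codeword}")
        seen.add(wc.codeword)
        ranked.append(wc.codeword)
    return _assign(table, ranked, initial.li)


def build_optimized_codebook(
    table: FrequencyTable,
    li: int,
    lib: PrimerLibrary,
    params: ConstraintParams = ConstraintParams(),
    region_nt: int = 8,
    include_reverse_complement: bool = False,
) -> Codebook:
    """Construct the primer-optimized codebook without materializing the full
    codeword set.

    Only the q lightest codewords are needed. Weighted codewords (those seen
    in primer windows) all have weight >= 1, so the q lightest are contained
    in the union of the weighted ones and the first q + (#weighted)
    lexicographic codewords — enumeration stops there, which keeps long
    codeword lengths tractable.
    """
    supply = count_codewords(li, params)
    if supply < table.q:
        raise ValueError(
            f"codeword supply {supply} at length {li} cannot cover q={table.q}"
        )
    windows = _primer_windows(lib, li, region_nt, include_reverse_complement)
    weighted = {w: c for w, c in windows.items() if _is_codeword(w, li, params)}
    budget = min(supply, table.q + len(weighted))
    candidates: dict[str, int] = {}
    for cw in iter_codewords(li, params):
        candidates[cw] = weighted.get(cw, 0)
        if len(candidates) >= budget:
            break
    candidates.update(weighted)  # weighted codewords beyond the lex budget
    ranked = sorted(candidates, key=lambda cw: (candidates[cw], cw))
    return _assign(table, ranked[: table.q], li)


def _is_codeword(word: str, li: int, params: ConstraintParams) -> bool:
    from .constraints import passes_biological_constraints

    return len(word) == li and passes_biological_constraints(word, params)
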