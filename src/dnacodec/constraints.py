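"""Alphabet handling and constraint predicates for synthesizable DNA.

Every stage of the codec consults the same two families of constraints:

* **Biological constraints** — GC content within a window (default 40–60%)
  and homopolymer runs capped (default: runs of 4+ identical bases are
  violations). Sequences outside these bounds are hard to synthesize and
  sequence reliably.
* **Nonspecific-pairing constraint** — a payload must not contain the
  3′-terminal k-mer (default k=8) of any primer in the random-access primer
  library. Eight or more consecutive bases complementary to a primer's 3′ end
  can seed spurious PCR extension; because hybridization is double-stranded, a
  *repeat* of the primer k-mer on one strand implies complementarity on the
  other, so the screen searches for the k-mer itself (and optionally its
  reverse complement).

Coordinates are 0-based, half-open. Input is normalized to uppercase; only
the DNA alphabet {A, C, G, T} is accepted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_sequence(seq: str) -> str:
    """Uppercase *seq* and verify it is over {A, C, G, T}.

    RNA (U) and ambiguity codes are rejected.
    """
    s = seq.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise ValueError(f"non-DNA symbols in sequence: {bad}")
    return s


def gc_content(seq: str) -> float:
    """Fraction of G and C bases in *seq*; errors on empty input."""
    s = normalize_sequence(seq)
    if not s:
        raise ValueError("GC content of an empty sequence is undefined")
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one repeated base (0 for empty input)."""
    s = normalize_sequence(seq)
    best = run = 0
    prev = ""
    for base in s:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


def reverse_complement(seq: str) -> str:
    """Watson–Crick complement, reversed. Involution."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConstraintParams:
    """Thresholds shared by every codec stage.

    Parameters
    ----------
    gc_min, gc_max:
        Inclusive GC-content window as fractions.
    max_homopolymer:
        Longest permitted run of identical bases, in nt. The default 3
        encodes the convention that runs of 4 or more are violations.
    nonspecific_k:
        Number of 3′-terminal primer bases whose contiguous occurrence in a
        payload counts as a nonspecific-pairing risk.
    check_reverse_complement:
        Whether risk detection also searches for the reverse complement of
        each primer 3′ k-mer.
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3
    nonspecific_k: int = 8
    check_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if self.nonspecific_k < 1:
            raise ValueError("nonspecific_k must be >= 1")


@dataclass
class NonspecificSite:
    """One occurrence of a primer 3′ k-mer inside a scanned sequence."""

    primer_id: str
    position: int  # 0-based start offset in the scanned sequence
    matched_kmer: str
    orientation: str  # "direct" | "reverse_complement"


@dataclass
class PrimerLibrary:
    """An orthogonal primer library used for random-access PCR retrieval.

    Primers are (id, sequence) pairs; 3′-terminal k-mers are derived on
    demand so they always reflect the current primer set and k.
    """

    primers: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for pid, seq in self.primers:
            s = normalize_sequence(seq)
            if not s:
                raise ValueError(f"primer {pid!r} is empty")
            cleaned.append((pid, s))
        self.primers = cleaned

    def __len__(self) -> int:
        return len(self.primers)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.primers)

    def three_prime_kmers(self, k: int) -> dict[str, str]:
        """Map primer id -> its last *k* bases; errors on short primers."""
        out: dict[str, str] = {}
        for pid, seq in self.primers:
            if len(seq) < k:
                raise ValueError(
                    f"primer {pid!r} is shorter ({len(seq)} nt) than the "
                    f"nonspecific k-mer length {k}"
                )
            out[pid] = seq[-k:]
        return out

    def digest(self) -> str:
        """Stable content hash, recorded in sidecar metadata."""
        h = hashlib.sha256()
        for pid, seq in sorted(self.primers):
            h.update(f"{pid}:{seq}\n".encode())
        return h.hexdigest()

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PrimerLibrary":
        records = SeqIO.parse(str(path), "fasta")
        return cls([(rec.id, str(rec.seq)) for rec in records])

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=pid, description="") for pid, seq in self.primers
        ]
        SeqIO.write(recs, str(path), "fasta")


def passes_biological_constraints(seq: str, params: ConstraintParams) -> bool:
    """True iff GC is within the window and no homopolymer run exceeds the cap."""
    s = normalize_sequence(seq)
    if not s:
        raise ValueError("cannot evaluate constraints on an empty sequence")
    if max_homopolymer_run(s) > params.max_homopolymer:
        return False
    return params.gc_min <= gc_content(s) <= params.gc_max


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1  # overlapping occurrences count


def find_nonspecific_sites(
    seq: str, lib: PrimerLibrary, params: ConstraintParams
) -> list[NonspecificSite]:
    """All occurrences of any primer 3′ k-mer inside *seq*.

    When ``params.check_reverse_complement`` is set, the reverse complement
    of each k-mer is searched as well. Results are sorted by position, then
    primer id; overlapping occurrences are all reported.
    """
    s = normalize_sequence(seq)
    k = params.nonspecific_k
    sites: list[NonspecificSite] = []
    for pid, kmer in lib.three_prime_kmers(k).items():
        for pos in _find_all(s, kmer):
            sites.append(NonspecificSite(pid, pos, kmer, "direct"))
        if params.check_reverse_complement:
            rc = reverse_complement(kmer)
            for pos in _find_all(s, rc):
                sites.append(NonspecificSite(pid, pos, rc, "reverse_complement"))
    sites.sort(key=lambda site: (site.position, site.primer_id, site.orientation))
    return sites


def has_nonspecific_site(seq: str, lib: PrimerLibrary, params: ConstraintParams) -> bool:
    """Fast boolean screen: does *seq* contain any primer 3′ k-mer?"""
    s = normalize_sequence(seq)
    k = params.nonspecific_k
    for kmer in lib.three_prime_kmers(k).values():
        if kmer in s:
            return True
        if params.check_reverse_complement and reverse_complement(kmer) in s:
            return True
    return False


def is_risk_free(seq: str, lib: PrimerLibrary, params: ConstraintParams) -> bool:
    """True iff *seq* passes biological constraints and contains no primer 3′ k-mer."""
    return passes_biological_constraints(seq, params) and not has_nonspecific_site(
        seq, lib, params
    )
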