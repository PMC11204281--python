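"""Seeded generators and the headline verification suite.

Real evaluations of a DNA-storage codec need a primer library and files to
encode; neither is bundled here, so both are generated reproducibly:

* :func:`generate_primer_library` rejection-samples constraint-satisfying
  primers with pairwise-distinct 3′ 8-mers (orthogonality proxy).
* :func:`generate_stream` produces binary streams with controlled block
  statistics — ``uniform`` (incompressible), ``constant`` (degenerate) and
  ``skewed_block`` (i.i.d. blocks from a small vocabulary under a Zipf or
  geometric law), the stand-in for compressible real files such as images,
  since high storage density is only reachable when the number of distinct
  scanned strings q is far below 2^l0.

:func:`run_headline_suite` executes four end-to-end experiments against the
codec's design bounds (payload GC window 40–60%, residual homopolymer
fraction <= 0.06%, nonspecific-pairing payload fraction <= 25%, theoretical
storage density >= 2.14 bits/nt) and reports one row per experiment. Every
generator is a pure function of its seed; the suite fans a master seed out
into per-experiment child seeds so each experiment is re-runnable alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import select_codebook_params
from .codec import CodecConfig, encode_bits
from .constraints import (
    ConstraintParams,
    PrimerLibrary,
    gc_content,
    has_nonspecific_site,
    max_homopolymer_run,
    passes_biological_constraints,
)

#: Upstream primer used as a named built-in fixture ("P1").
REFERENCE_PRIMER_ID = "P1"
REFERENCE_PRIMER = "AATTGACGTATTGCTCGACC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reference_primer_library() -> PrimerLibrary:
    """Single-primer library holding the built-in reference primer."""
    return PrimerLibrary([(REFERENCE_PRIMER_ID, REFERENCE_PRIMER)])


def generate_primer_library(
    n: int,
    length: int = 20,
    seed: int = 0,
    params: ConstraintParams = ConstraintParams(),
    max_attempts_per_primer: int = 10_000,
) -> PrimerLibrary:
    """Random orthogonal-ish primer library.

    Each primer passes the biological constraints and has a 3′
    ``params.nonspecific_k``-mer distinct from every other primer's.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < params.nonspecific_k:
        raise ValueError("primer length must be >= the nonspecific k-mer length")
    rng = np.random.default_rng(seed)
    primers: list[tuple[str, str]] = []
    seen_kmers: set[str] = set()
    attempts = 0
    while len(primers) < n:
        attempts += 1
        if attempts > max_attempts_per_primer * n:
            raise ValueError(
                f"could not sample {n} primers of length {length} under the "
                "constraints; parameters look infeasible"
            )
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        if not passes_biological_constraints(seq, params):
            continue
        kmer = seq[-params.nonspecific_k :]
        if kmer in seen_kmers:
            continue
        seen_kmers.add(kmer)
        primers.append((f"P{len(primers) + 1}", seq))
    return PrimerLibrary(primers)


@dataclass(frozen=True)
class StreamSpec:
    """Recipe for a reproducible synthetic bit stream."""

    kind: str  # "uniform" | "skewed_block" | "constant"
    total_bits: int
    block_bits: int | None = None
    vocabulary_size: int | None = None
    probability_law: str = "zipf"  # "zipf" | "geometric" | "custom"
    zipf_exponent: float = 1.0
    geometric_ratio: float = 0.5
    custom_probs: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_bits <= 0:
            raise ValueError("total_bits must be positive")
        if self.kind == "skewed_block":
            if not self.block_bits or not self.vocabulary_size:
                raise ValueError("skewed_block needs block_bits and vocabulary_size")
            if self.vocabulary_size > 2 ** self.block_bits:
                raise ValueError("vocabulary_size exceeds 2^block_bits")
        elif self.kind not in ("uniform", "constant"):
            raise ValueError(f"unknown stream kind {self.kind!r}")


def _law_probabilities(spec: StreamSpec) -> np.ndarray:
    v = spec.vocabulary_size
    assert v is not None
    if spec.probability_law == "zipf":
        p = 1.0 / np.arange(1, v + 1, dtype=float) ** spec.zipf_exponent
    elif spec.probability_law == "geometric":
        p = spec.geometric_ratio ** np.arange(v, dtype=float)
    elif spec.probability_law == "custom":
        if spec.custom_probs is None or len(spec.custom_probs) != v:
            raise ValueError("custom law needs vocabulary_size probabilities")
        p = np.asarray(spec.custom_probs, dtype=float)
    else:
        raise ValueError(f"unknown probability law {spec.probability_law!r}")
    return p / p.sum()


def generate_stream(spec: StreamSpec) -> str:
    """Deterministic bit stream per *spec* (pure function of spec incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "constant":
        return "0" * spec.total_bits
    if spec.kind == "uniform":
        arr = rng.integers(0, 2, size=spec.total_bits).astype(np.uint8)
        return (arr + ord("0")).astype(np.uint8).tobytes().decode("ascii")
    # skewed_block: i.i.d. blocks from a fixed vocabulary
    b = spec.block_bits
    v = spec.vocabulary_size
    assert b is not None and v is not None
    seen: set[int] = set()
    vocab: list[int] = []
    while len(vocab) < v:  # distinct block values, insertion-ordered
        for x in rng.integers(0, 2 ** b, size=v):
            xi = int(x)
            if xi not in seen:
                seen.add(xi)
                vocab.append(xi)
                if len(vocab) == v:
                    break
    vocab_strings = [format(x, f"0{b}b") for x in sorted(vocab)]
    probs = _law_probabilities(spec)
    n_blocks = -(-spec.total_bits // b)  # ceil
    draws = rng.choice(v, size=n_blocks, p=probs)
    return "".join(vocab_strings[i] for i in draws)[: spec.total_bits]


# ---------------------------------------------------------------------------
# headline experiments
# ---------------------------------------------------------------------------


def _child_seeds(master_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def experiment_gc_homopolymer(
    seed: int,
    n_streams: int = 1000,
    stream_bits: int = 1000,
    lib: PrimerLibrary | None = None,
    n_primers: int = 50,
) -> dict:
    """Encode many short uniform random streams; measure payload GC extremes
    and the fraction of payloads with a homopolymer run past the cap."""
    lib_seed, stream_seed = _child_seeds(seed, 2)
    library = lib or generate_primer_library(n_primers, seed=lib_seed)
    params = ConstraintParams()
    cfg = CodecConfig(params=params)
    gc_min_seen, gc_max_seen = 1.0, 0.0
    violating = 0
    n_payloads = 0
    for i in range(n_streams):
        bits = generate_stream(
            StreamSpec(kind="uniform", total_bits=stream_bits, seed=stream_seed + i)
        )
        records, _ = encode_bits(bits, library, cfg)
        for r in records:
            gc = gc_content(r.payload)
            gc_min_seen = min(gc_min_seen, gc)
            gc_max_seen = max(gc_max_seen, gc)
            if max_homopolymer_run(r.payload) > params.max_homopolymer:
                violating += 1
            n_payloads += 1
    return {
        "n_streams": n_streams,
        "n_payloads": n_payloads,
        "gc_min": gc_min_seen,
        "gc_max": gc_max_seen,
        "homopolymer_fraction": violating / n_payloads,
    }


def experiment_nonspecific_pairing(
    seed: int,
    file_bits: int = 800_000,
    n_primers: int = 50,
    payload_nt: int = 200,
) -> dict:
    """Encode one large uniform random stream against a primer library;
    measure the fraction of payloads still containing any primer 3′ 8-mer
    after interleaver correction."""
    lib_seed, stream_seed = _child_seeds(seed, 2)
    library = generate_primer_library(n_primers, seed=lib_seed)
    params = ConstraintParams()
    bits = generate_stream(
        StreamSpec(kind="uniform", total_bits=file_bits, seed=stream_seed)
    )
    records, _ = encode_bits(
        bits, library, CodecConfig(payload_nt=payload_nt, params=params)
    )
    risky = sum(
        1 for r in records if has_nonspecific_site(r.payload, library, params)
    )
    return {
        "n_payloads": len(records),
        "risky_payloads": risky,
        "pairing_fraction": risky / len(records),
    }


def experiment_storage_density(
    seed: int,
    total_bits: int = 4_000_000,
    block_bits: int = 24,
    vocabulary_size: int = 50,
) -> dict:
    """Theoretical storage density selected for a compressible (skewed-block
    Zipf) stream."""
    (stream_seed,) = _child_seeds(seed, 1)
    bits = generate_stream(
        StreamSpec(
            kind="skewed_block",
            total_bits=total_bits,
            block_bits=block_bits,
            vocabulary_size=vocabulary_size,
            probability_law="zipf",
            seed=stream_seed,
        )
    )
    record, _, _ = select_codebook_params(bits)
    return {
        "total_bits": total_bits,
        "l0": record.l0,
        "li": record.li,
        "density": record.density,
    }


def run_headline_suite(seed: int = 1, **scale_overrides) -> pd.DataFrame:
    """Run the four headline experiments and tabulate values against bounds.

    ``scale_overrides`` forwards size keywords to individual experiments
    (exploration only; the defaults are the reference configuration).
    """
    s1, s2, s3 = _child_seeds(seed, 3)
    gc_keys = {"n_streams", "stream_bits", "n_primers"}
    gc = experiment_gc_homopolymer(
        s1, **{k: v for k, v in scale_overrides.items() if k in gc_keys}
    )
    ns_keys = {"file_bits", "payload_nt"}
    ns = experiment_nonspecific_pairing(
        s2, **{k: v for k, v in scale_overrides.items() if k in ns_keys}
    )
    dens_keys = {"total_bits", "block_bits", "vocabulary_size"}
    dens = experiment_storage_density(
        s3, **{k: v for k, v in scale_overrides.items() if k in dens_keys}
    )
    rows = [
        ("gc_min_pct", 100 * gc["gc_min"], ">=", 40.0, gc["n_payloads"]),
        ("gc_max_pct", 100 * gc["gc_max"], "<=", 60.0, gc["n_payloads"]),
        (
            "homopolymer_residual_pct",
            100 * gc["homopolymer_fraction"],
            "<=",
            0.06,
            gc["n_payloads"],
        ),
        (
            "nonspecific_payload_pct",
            100 * ns["pairing_fraction"],
            "<=",
            25.0,
            ns["n_payloads"],
        ),
        (
            "storage_density_bits_per_nt",
            dens["density"],
            ">=",
            2.14,
            dens["total_bits"],
        ),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value", "cmp", "bound", "n"])
    df["passed"] = [
        v <= b if c == "<=" else v >= b
        for v, c, b in zip(df["value"], df["cmp"], df["bound"])
    ]
    return df
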