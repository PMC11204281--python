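"""End-to-end file <-> DNA pipeline.

Encoding: file bytes -> bit stream -> adaptive codebook selection
(density-optimal l0/li) -> primer-optimized string→codeword mapping ->
codeword concatenation -> fixed-length payload segmentation -> per-payload
interleaver correction -> oligo pool (FASTA) plus sidecar metadata (JSON).

Decoding inverts each step exactly: de-interleave per record, concatenate,
split into li-nt codewords, inverse-map, strip stream padding, repack bytes.
The sidecar carries everything the decoder needs — the codebook, padding
counts, segment length and per-record interleave iterations — so decode is
byte-exact and needs neither the primer library nor any re-derivation.

Record order is carried in FASTA headers (``record_<index>|iters=<k>|risk=<0/1>``)
and the sidecar, not embedded as index bases inside the oligos, keeping
payloads purely codebook-governed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codebook import (
    Codebook,
    DensityRecord,
    pad_stream,
    select_codebook_params,
)
from .constraints import (
    ConstraintParams,
    PrimerLibrary,
    find_nonspecific_sites,
    gc_content,
    max_homopolymer_run,
)
from .interleaver import correct_sequence
from .primer_weights import build_optimized_codebook

DEFAULT_PAYLOAD_NT = 200
_TWO_BIT = {"00": "A", "01": "C", "10": "G", "11": "T"}
_TWO_BIT_INV = {v: k for k, v in _TWO_BIT.items()}


def bytes_to_bits(data: bytes) -> str:
    """Most-significant-bit-first bit string of *data*."""
    if not data:
        return ""
    arr = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    return (arr + ord("0")).astype(np.uint8).tobytes().decode("ascii")


def bits_to_bytes(bits: str, bit_count: int) -> bytes:
    """Inverse of :func:`bytes_to_bits` for the first *bit_count* bits."""
    if bit_count % 8:
        raise ValueError(f"bit_count {bit_count} is not a whole number of bytes")
    if bit_count > len(bits):
        raise ValueError(
            f"bit_count {bit_count} exceeds available bits {len(bits)}"
        )
    if bit_count == 0:
        return b""
    arr = np.frombuffer(bits[:bit_count].encode("ascii"), dtype=np.uint8) - ord("0")
    if arr.max() > 1:
        raise ValueError("bit stream must contain only '0' and '1'")
    return np.packbits(arr).tobytes()


def encode_stream(bits: str, codebook: Codebook) -> str:
    """Map each l0-bit block of a padded stream to its codeword."""
    l0 = codebook.l0
    if len(bits) % l0:
        raise ValueError("stream length must be a multiple of l0; pad first")
    forward = codebook.forward
    try:
        return "".join(
            forward[bits[i : i + l0]] for i in range(0, len(bits), l0)
        )
    except KeyError as exc:
        raise ValueError(
            f"block {exc.args[0]!r} absent from the codebook; the codebook "
            "must be built from the same stream"
        ) from None


def segment_payloads(seq: str, payload_nt: int = DEFAULT_PAYLOAD_NT) -> list[str]:
    """Cut the coded sequence into synthesizable oligo payloads."""
    if payload_nt < 20:
        raise ValueError("payload_nt must be >= 20")
    return [seq[i : i + payload_nt] for i in range(0, len(seq), payload_nt)]


@dataclass
class EncodedRecord:
    """One oligo of the pool plus its correction bookkeeping."""

    index: int
    payload: str
    interleave_iterations: int
    pad_nt: int  # interleaver filler bases inside the payload
    residual_risk: bool


@dataclass
class CodecConfig:
    payload_nt: int = DEFAULT_PAYLOAD_NT
    scan_min: int = 3
    scan_max: int = 30
    max_interleave_iters: int = 16
    params: ConstraintParams = field(default_factory=ConstraintParams)


@dataclass
class SidecarMetadata:
    """Everything required to invert an encoding byte-exactly."""

    l0: int
    li: int
    codebook: dict[str, str]  # bitstring -> codeword
    stream_bits: int  # L0: original bit count (8 * file bytes)
    stream_pad_bits: int
    payload_nt: int
    records: list[dict]  # per record: index, iterations, pad_nt, residual_risk
    params: dict
    primer_digest: str
    density: dict  # the selected DensityRecord

    def to_json(self) -> str:
        payload = asdict(self)
        payload["codebook"] = dict(sorted(self.codebook.items()))
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SidecarMetadata":
        try:
            raw = json.loads(text)
            return cls(**raw)
        except (json.JSONDecodeError, TypeError) as exc:
            raise ValueError(f"corrupt sidecar: {exc}") from exc

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "SidecarMetadata":
        return cls.from_json(Path(path).read_text())


def _interleave_unit(chunk_nt: int, li: int) -> int:
    """Codeword-aligned interleaving when the payload is a whole number of
    codewords; base-level otherwise."""
    return li if chunk_nt % li == 0 else 1


def encode_bits(
    bits: str,
    lib: PrimerLibrary,
    config: CodecConfig | None = None,
) -> tuple[list[EncodedRecord], SidecarMetadata]:
    """Encode a raw bit stream; the workhorse behind :func:`encode_file`."""
    if not bits:
        raise ValueError("cannot encode an empty stream")
    cfg = config or CodecConfig()
    record, _, table = select_codebook_params(
        bits, cfg.params, cfg.scan_min, cfg.scan_max
    )
    codebook = build_optimized_codebook(table, record.li, lib, cfg.params)
    padded = pad_stream(bits, record.l0)
    dna = encode_stream(padded, codebook)
    records: list[EncodedRecord] = []
    for i, chunk in enumerate(segment_payloads(dna, cfg.payload_nt)):
        corrected, plan, residual = correct_sequence(
            chunk, lib, cfg.params, cfg.max_interleave_iters,
            unit_nt=_interleave_unit(len(chunk), record.li),
        )
        iters = plan.iterations if plan else 0
        records.append(
            EncodedRecord(
                index=i,
                payload=corrected,
                interleave_iterations=iters,
                pad_nt=plan.pad_nt if plan and iters else 0,
                residual_risk=residual,
            )
        )
    sidecar = SidecarMetadata(
        l0=record.l0,
        li=record.li,
        codebook=dict(codebook.forward),
        stream_bits=len(bits),
        stream_pad_bits=len(padded) - len(bits),
        payload_nt=cfg.payload_nt,
        records=[
            {
                "index": r.index,
                "iterations": r.interleave_iterations,
                "pad_nt": r.pad_nt,
                "residual_risk": r.residual_risk,
            }
            for r in records
        ],
        params=asdict(cfg.params),
        primer_digest=lib.digest(),
        density=asdict(record),
    )
    return records, sidecar


def encode_file(
    data: bytes,
    lib: PrimerLibrary,
    config: CodecConfig | None = None,
) -> tuple[list[EncodedRecord], SidecarMetadata]:
    """Encode arbitrary file bytes into an oligo pool plus sidecar."""
    if not data:
        raise ValueError("cannot encode an empty file")
    return encode_bits(bytes_to_bits(data), lib, config)


def decode_bits(records: list[EncodedRecord], sidecar: SidecarMetadata) -> str:
    """Recover the original bit stream from a pool and its sidecar."""
    from .interleaver import deinterleave, plan_interleaver

    by_index = {r.index: r for r in records}
    if len(by_index) != len(records):
        raise ValueError("duplicate record indices in pool")
    expected = {meta["index"] for meta in sidecar.records}
    missing = expected - set(by_index)
    if missing:
        raise ValueError(f"missing record indices: {sorted(missing)}")

    inverse = {cw: s for s, cw in sidecar.codebook.items()}
    if len(inverse) != len(sidecar.codebook):
        raise ValueError("corrupt sidecar: codebook is not injective")
    li = sidecar.li
    pieces: list[str] = []
    for meta in sorted(sidecar.records, key=lambda m: m["index"]):
        rec = by_index[meta["index"]]
        payload = rec.payload
        iters = meta["iterations"]
        if iters:
            base_len = len(payload) - meta["pad_nt"]
            plan = plan_interleaver(base_len, _interleave_unit(base_len, li))
            payload = deinterleave(payload, plan, iterations=iters)
        pieces.append(payload)
    dna = "".join(pieces)
    if len(dna) % li:
        raise ValueError("reassembled sequence length is not a multiple of li")
    bit_chunks: list[str] = []
    for i in range(0, len(dna), li):
        cw = dna[i : i + li]
        try:
            bit_chunks.append(inverse[cw])
        except KeyError:
            raise ValueError(f"unknown codeword {cw!r} at offset {i}") from None
    bits = "".join(bit_chunks)
    return bits[: sidecar.stream_bits]


def decode_file(records: list[EncodedRecord], sidecar: SidecarMetadata) -> bytes:
    """Byte-exact inverse of :func:`encode_file`."""
    bits = decode_bits(records, sidecar)
    return bits_to_bytes(bits, sidecar.stream_bits)


# ---------------------------------------------------------------------------
# pool I/O and auditing
# ---------------------------------------------------------------------------


def write_pool_fasta(records: list[EncodedRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.payload),
            id=f"record_{r.index}|iters={r.interleave_iterations}|risk={int(r.residual_risk)}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_pool_fasta(path: str | Path, sidecar: SidecarMetadata | None = None) -> list[EncodedRecord]:
    records = []
    pad_by_index = (
        {m["index"]: m["pad_nt"] for m in sidecar.records} if sidecar else {}
    )
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        index = int(fields[0].removeprefix("record_"))
        iters = int(fields[1].removeprefix("iters="))
        risk = bool(int(fields[2].removeprefix("risk=")))
        records.append(
            EncodedRecord(
                index=index,
                payload=str(rec.seq),
                interleave_iterations=iters,
                pad_nt=pad_by_index.get(index, 0),
                residual_risk=risk,
            )
        )
    return records


def audit_pool(
    records: list[EncodedRecord],
    lib: PrimerLibrary,
    params: ConstraintParams = ConstraintParams(),
    sidecar: SidecarMetadata | None = None,
) -> dict:
    """Per-record and aggregate pool statistics.

    Reports nonspecific site counts, the fraction of records carrying at
    least one site, GC statistics, a homopolymer-run histogram and — when a
    sidecar is supplied — the achieved density (stream bits per emitted nt)
    next to the theoretical density of the selected configuration.
    """
    import pandas as pd

    rows = []
    run_hist: dict[int, int] = {}
    for r in records:
        sites = find_nonspecific_sites(r.payload, lib, params)
        run = max_homopolymer_run(r.payload)
        run_hist[run] = run_hist.get(run, 0) + 1
        rows.append(
            {
                "index": r.index,
                "length_nt": len(r.payload),
                "gc": gc_content(r.payload),
                "max_run": run,
                "nonspecific_sites": len(sites),
                "interleave_iterations": r.interleave_iterations,
                "residual_risk": r.residual_risk,
            }
        )
    per_record = pd.DataFrame(rows)
    total_nt = int(per_record["length_nt"].sum()) if rows else 0
    aggregate = {
        "n_records": len(records),
        "total_payload_nt": total_nt,
        "pairing_fraction": (
            float((per_record["nonspecific_sites"] > 0).mean()) if rows else 0.0
        ),
        "gc_mean": (
            float(
                (per_record["gc"] * per_record["length_nt"]).sum() / total_nt
            )
            if total_nt
            else float("nan")
        ),
        "gc_min": float(per_record["gc"].min()) if rows else float("nan"),
        "gc_max": float(per_record["gc"].max()) if rows else float("nan"),
        "homopolymer_violation_fraction": (
            float((per_record["max_run"] > params.max_homopolymer).mean())
            if rows
            else 0.0
        ),
        "run_histogram": dict(sorted(run_hist.items())),
    }
    if sidecar is not None and total_nt:
        # codebook footprint counted alongside payloads, mirroring the
        # theoretical density's accounting, so achieved <= theoretical holds
        aggregate["achieved_density"] = sidecar.stream_bits / (
            total_nt + sidecar.density["codebook_nt"]
        )
        aggregate["theoretical_density"] = sidecar.density["density"]
    return {"per_record": per_record, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# trivial 2-bit baseline (comparison plumbing, no constraint handling)
# ---------------------------------------------------------------------------


def baseline_two_bit_encode(data: bytes) -> str:
    """Fixed A=00, C=01, G=10, T=11 transcoding at exactly 2 bits/nt."""
    bits = bytes_to_bits(data)
    return "".join(_TWO_BIT[bits[i : i + 2]] for i in range(0, len(bits), 2))


def baseline_two_bit_decode(seq: str) -> bytes:
    bits = "".join(_TWO_BIT_INV[b] for b in seq)
    return bits_to_bytes(bits, len(bits))
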