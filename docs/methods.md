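# Methods

This note documents the model implemented by `dnacodec`, the default
parameters and their rationale, the synthetic workloads used for
verification, and the limitations of both.

## 1. Constraint model

A payload sequence is *biologically compliant* when

- its GC fraction lies in [`gc_min`, `gc_max`] = [0.40, 0.60], and
- its longest homopolymer run is at most `max_homopolymer` = 3 nt.

It is additionally *pairing-safe* with respect to a primer library when it
contains no primer's 3′-terminal `nonspecific_k` = 8 nt substring. With
`check_reverse_complement = True` (the detection default) the reverse
complement of each 3′ 8-mer is screened as well, covering annealing to
either strand of the double-stranded amplicon. All three thresholds are the
values commonly used for oligo pools amplified by PCR and read on
short-read or nanopore platforms; they are configurable through
`ConstraintParams` but the defaults define the reference study.

GC bounds are compared with a 1e-9 epsilon so that exact-boundary
compositions (e.g. 2 GC in 5 nt at a 0.40 bound) are classified by their
rational value, not by floating-point rounding.

## 2. Adaptive codebook construction

### 2.1 Valid codeword space

For codeword length *l*, the valid set is all 4^*l* strings whose GC count
lies in [⌈*l*·gc_min⌉, ⌊*l*·gc_max⌋] and whose runs are ≤ 3. The count is
computed exactly by dynamic programming over states
(position, GC count, last base, current run length); enumeration uses a
depth-first lexicographic generator with exact feasibility pruning (a
branch is extended only if the DP certifies at least one completion).
Enumeration is only ever materialized up to *l* = 16; all larger-*l*
decisions use the DP count. A brute-force filter over all 4^*l* strings
serves as the test oracle for *l* ≤ 8. Notable values: *l* = 2 has 8 valid
codewords (all dinucleotides with exactly one G/C), *l* = 3 has none (no
integer GC count lies in [1.2, 1.8]), *l* = 4 has 96.

### 2.2 Block-length scan

The bit stream is scanned at every block length *l*₀ in [`scan_min`,
`scan_max`] = [3, 30]. For each *l*₀ the stream (zero-padded to a multiple
of *l*₀; pad recorded) is cut into non-overlapping blocks and the *q*
distinct blocks are tabulated with numpy (`frombuffer`/`reshape`/matrix
product against bit weights), making the full scan on multi-megabit
streams take about a second. The codeword length *l*ᵢ is the smallest
*l* ≤ 16 whose valid-codeword count is ≥ *q*. Density is

D(*l*₀) = *L*₀ / (*L*′ + *L*c), *L*′ = (*L*₀/*l*₀)·*l*ᵢ, *L*c = *q*(*l*₀+*l*ᵢ),

in bits per nucleotide; the codebook footprint *L*c charges each dictionary
entry with its bit string (*l*₀ bits, counted at one nucleotide-equivalent
per bit for accounting purposes) and its codeword. The scan keeps
the maximal D, breaking ties toward smaller (*l*₀, *l*ᵢ). The scan range
cap of 30 bounds worst-case dictionary size at 2^30 only in principle; in
practice *q* is bounded by *L*₀/*l*₀ and by the *l*ᵢ ≤ 16 supply cap, and
streams whose *q* exceeds the largest supply at a given *l*₀ simply
disqualify that *l*₀.

### 2.3 Primer-aware codeword assignment

Each valid codeword of length *l*ᵢ receives a weight: the number of times
it occurs as an *l*ᵢ-window (stride 1) within the 3′-terminal 8 nt of each
primer (a single window of the last *l*ᵢ bases when *l*ᵢ > 8). Windows that
are not valid codewords contribute nothing. Weighting uses the direct
orientation by default — the 3′ 8-mer itself is what invades a payload —
with reverse-complement weighting available as an explicit option. Bit
blocks sorted by descending frequency are assigned codewords sorted by
(weight ascending, lexicographic): the bulk of the stream is written with
codewords that resemble primer 3′ ends least. The assignment never
materializes the full codeword set: weight-0 codewords sort before all
weighted ones, so the *q* lightest codewords are provably contained in the
union of the weighted set and the first *q* + |weighted| codewords in
lexicographic order, which the lazy generator produces directly.

## 3. Segmentation and constraint repair

The encoded stream is segmented into payloads of `payload_nt` = 200 nt
(tail shorter), a typical synthesizable oligo length. Payloads that are
already compliant and pairing-safe are left untouched. A violating payload
enters the four-block interleaver:

1. The payload (padded with a neutral `ATGC` filler to the next usable
   length if needed; pad recorded) fills an N×M grid row-major with
   N·M = cell count, N ≠ M, N ≥ M and |N − M| minimal over all pads tried
   in increasing order. Square grids are excluded because their symmetric
   readout moves too few elements.
2. The grid splits into four unequal sub-blocks via n₁+n₂ = N, m₁+m₂ = M
   with n₁ > n₂ (even X → (X/2+1, X/2−1); X = 2 → (2, 0), leaving two
   empty sub-blocks that the readout handles naturally).
3. Sub-block readouts differ deliberately: top-left column-major,
   top-right 180° rotation, bottom-left snake (boustrophedon), bottom-right
   reversed column-major. The concatenation of the four readouts is the
   interleaved payload.
4. Powers of this fixed permutation are applied in sequence (up to
   `max_interleave_iters` = 16). The first power yielding a compliant,
   pairing-safe arrangement is kept. If none does, the power with the best
   (fewest pairing sites, then fewest run violations) score is kept and the
   record is flagged `residual_risk`. The applied power is stored per
   record, so decoding applies the exact inverse (argsort of the
   permutation, iterated).

### 3.1 Codeword-aligned units

A design deviation from the base-level formulation, adopted after
measurement: permuting individual nucleotides destroys the codeword
structure that guarantees compliance — on encoded payloads, roughly 63 % of
base-level arrangements introduce a homopolymer run ≥ 4 nt, so base-level
repair converts pairing violations into run violations. Moreover the
permutation's cycle order is small (6–12 for typical payload lengths), so
the 16 powers revisit only a handful of distinct arrangements.

The interleaver therefore operates on cells of `unit_nt` nucleotides; the
codec sets `unit_nt = l`ᵢ whenever *l*ᵢ divides the payload length (else it
falls back to single-base cells). Cell-aligned rearrangement permutes whole
codewords: per-codeword GC balance is conserved exactly, and at *l*ᵢ = 2 no
arrangement can create a run ≥ 3 because every valid dinucleotide has two
distinct bases. With this alignment the measured residual homopolymer rate
drops from ≈ 2.3 % of payloads to 0, while the pairing-repair behaviour is
unchanged. The base-level mode remains available (`unit_nt = 1`, the
default of `plan_interleaver`).

## 4. Decoding and auditing

Decoding reverses each record (de-interleave by the recorded power, strip
pad), concatenates in index order, strips stream pad, inverts the codebook,
and repacks bits MSB-first into bytes; a missing or duplicate record index
is a hard error. Encoding is fully deterministic — identical input bytes,
primer library, and configuration give byte-identical FASTA and sidecar
output — so no seed appears in the codec itself.

`audit_pool` recomputes, independently of the encoder, per-record GC, run
lengths, and pairing sites, plus aggregates. The *achieved density* is
defined as stream bits divided by (total payload nt + codebook footprint
nt). Including the codebook footprint in the denominator keeps the invariant
*achieved ≤ theoretical* valid for small files, where the dictionary is a
non-negligible fraction of the synthesized material; a definition without
the footprint would exceed the theoretical value whenever padding losses
are smaller than the dictionary share.

## 5. Verification workloads

The headline suite (`dnacodec.fixtures.run_headline_suite`, also exposed as
`scripts/acceptance.py` and `dnacodec verify`) measures four quantities at
a fixed reference configuration. All randomness fans out from one master
seed through `numpy.random.default_rng` child seeds (< 2³¹).

1. **GC and homopolymer statistics** — 1000 independent 1000-bit uniform
   Bernoulli(½) streams, each run through the full pipeline against a
   50-primer library; reported are the extreme per-payload GC percentages
   and the percentage of payloads with a run ≥ 4 nt.
2. **Nonspecific pairing** — one 100 kB uniform file, 50 seeded primers
   (20 nt, compliant, distinct 3′ 8-mers, rejection-sampled), 200-nt
   payloads; reported is the percentage of payloads still containing a
   primer 3′ 8-mer after repair.
3. **Storage density** — a 500 kB stream of 24-bit blocks drawn from a
   50-word vocabulary under a Zipf(1.0) law, emulating structured (e.g.
   text-like) data; reported is the selected theoretical density.

What the generators emulate: the statistical profile of random (compressed
or encrypted) payloads, and of redundant structured data, plus a realistic
primer library geometry. What they do not emulate: synthesis/sequencing
error channels, strand dropout, primer cross-dimerization, secondary
structure, or melting-temperature design — no error-correcting code is
included, and the pairing screen is purely substring-based (no
thermodynamic model).

Measured values at seed 1: GC exactly 50 % on every payload (uniform
streams select *l*ᵢ = 2, and all valid dinucleotides are exactly half GC),
homopolymer residual 0 %, nonspecific payload fraction 2.38 % (n = 2223
payloads), density 5.99 bits/nt (the Zipf stream has ≪ 2²⁴ distinct
blocks, so 24-bit blocks map to 4-nt codewords). The pairing fraction and
density vary with seed within a narrow band; the GC and run statistics are
structural.

## 6. Numerical and implementation choices

- Bit packing via `numpy.packbits`/`unpackbits`, MSB-first.
- Exact integer DP with `lru_cache` for codeword counting; no floating
  point in feasibility decisions.
- GC-window comparisons with a 1e-9 epsilon (see §1); density comparisons
  in tests use the same tolerance.
- FASTA I/O through Biopython; sidecar metadata as sorted-key JSON for
  byte-stable output.
- Derived seeds are drawn uniformly below 2³¹ so they remain valid for any
  32-bit-seeded consumer.

## 7. Limitations

- Payloads whose constraint violation is compositional (e.g. GC outside
  the window due to stream pad or filler interaction) cannot be repaired
  by any rearrangement; they are returned flagged, not dropped. Downstream
  users must check `residual_risk` / the audit report.
- A payload shorter than 6 cells cannot be gridded; it is returned
  unmodified and flagged if risky. With the default 200-nt payloads this
  affects at most one tail record of very small files.
- The density accounting charges the dictionary at 1 bit per stored bit of
  the block string; a synthesized dictionary would itself need transcoding,
  which this model does not include.
- The problem sizes in §5 are this package's reference configuration,
  chosen to be large enough for stable percentages while keeping the full
  suite within seconds; they are fixed in code rather than exposed as
  script options to keep reported numbers comparable across runs.
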