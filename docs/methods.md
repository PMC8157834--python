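# Methods

This note documents the models, parameter choices and numerical
conventions behind each `asvpost` stage, and what the synthetic
generators do and do not emulate.

## Crosstalk (index-hopping) removal

**Model.** Reads misassigned during demultiplexing are assumed to leak
*uniformly* across samples: feature *i* with total count C_i over N
samples has expected per-sample leak e_i = γ·C_i/N. Each positive entry
x_ij gets a crosstalk score

    s_ij = e_i / (e_i + x_ij)  ∈ (0, 1],

which equals ½ when the observation matches the expectation and is
strictly decreasing in x_ij. Entries with s_ij ≥ τ are flagged; flagged
entries are set to zero. Ties at the threshold are flagged (≥), i.e.
conservative toward removing suspicious minima.

**Why zeroing, not subtraction.** Subtracting an expected leak from every
entry would produce fractional, non-reproducible counts and would modify
entries that are clearly genuine. The harm crosstalk does is *spurious
presence* (inflated richness/diversity), which zeroing addresses
directly; abundances of genuine entries are left untouched.

**Parameters.**

| parameter      | default | meaning |
|----------------|---------|---------|
| `gamma`        | 0.01    | leaked fraction of each feature's reads; order of magnitude of published index-hopping rates on patterned flow cells |
| `tau`          | 1/3     | score threshold; τ = 1/3 ⇔ flag x_ij ≤ 2·e_i, a "within twofold of expectation" cut |
| `max_row_loss` | 0.1     | if flagged entries sum to more than this fraction of C_i, the row is skipped (reported, never altered) — protects genuinely low, evenly spread features from wholesale erasure |
| `min_total`    | 1       | rows with C_i below this are skipped |

A feature is *reported* as skipped only when a guard actually protected a
flagged entry; rows with nothing to remove (including all-zero rows) are
not skip events.

**Properties the implementation guarantees** (and the tests verify):
identity at γ = 0; elementwise output ≤ input; integer counts preserved;
within-row monotonicity (if a count a is zeroed, any smaller positive
count in the same row is zeroed too — immediate from monotonicity of s);
row-scale covariance (multiplying a row by k scales e_i with C_i and
leaves the zero/keep pattern unchanged). The vectorised implementation is
checked against an independent scalar-loop evaluation of the same
formulas on hundreds of random tables.

Scores are compared in double precision; an entry lying exactly at
x_ij = 2·e_i evaluates to a correctly rounded 1/3 and is flagged, and the
oracle uses the identical expression, so agreement is exact.

Out of scope by design: estimating γ from spike-ins or mock communities,
and lane-/index-structured (non-uniform) leakage.

## Merging N-concatenated pairs

**Spacer detection.** A sequence splits when it contains exactly one
maximal run of ≥ `spacer_min_run` Ns (default 5), strictly internal, with
N-free flanks. DADA2-style concatenation emits 10 Ns; tolerating ≥ 5 is
robust to upstream trimming, while isolated ambiguity Ns (runs < 5) never
split. Two or more qualifying runs are ambiguous: the sequence passes
through with a warning.

**Overlap merge.** Candidate overlap lengths L run from
min(|left|, |right|) *downward* to `min_overlap` (default 12); the
length-L suffix of the left fragment is compared to the length-L prefix
of the right one, and the first L with mismatches ≤ ⌊`max_mismatch_fraction`·L⌋
is accepted, yielding `left + right[L:]` (length law
|merged| = |left| + |right| − L). Preferring the longest overlap
minimises spurious short-homology joins. At mismatching positions the
left (forward-read-derived) base is kept — forward reads are
conventionally higher quality and no per-base qualities survive
denoising. The default mismatch tolerance is 0 because denoised ASVs are
consensus sequences; the knob exists for noisy inputs. No
reverse-complementation is performed: concatenation upstream already
orients the right fragment.

**Table update.** After resolution, features with identical final
sequences are collapsed: counts are summed elementwise (per-sample column
totals are exactly conserved — a hard invariant), the surviving feature
keeps the ID of the member with the largest total (ties: first in input
order) and that member's taxonomy row. The operation is idempotent:
merged sequences contain no qualifying spacer.

## Octave histograms

A count c ≥ 1 in a sample falls in bin k = ⌊log2 c⌋, i.e. bins are
[2^k, 2^(k+1)). Binning uses integer bit length, never floating-point
logarithms, so it is exact for arbitrarily large counts. Zero counts are
excluded, so per-sample bin totals equal the number of detected features
in that sample. Raw counts are binned (not normalised ones): the plot is
a per-sample quality diagnostic, and normalisation would mix samples'
depths into it. The tidy TSV is the primary output; per-sample bar charts
are a best-effort convenience.

## Exports

Dialects are pinned byte-exact and covered by golden-header tests:
MicrobiomeAnalyst wants comma-separated files opening with `#NAME`
(abundance, metadata) and `#TAXONOMY` + the seven canonical ranks
(taxonomy); Rhea wants one tab-separated table opening with `#OTUId`,
optionally ending in a `taxonomy` column with the `;`-joined lineage
(trailing empty ranks keep their separators). Counts are never altered:
re-parsing an exported abundance file reproduces the source matrix
exactly. IDs containing a comma are CSV-quoted for MicrobiomeAnalyst;
IDs containing a tab are rejected for Rhea, which has no quoting
convention. File names (`abundance.csv`, `taxonomy.csv`, `metadata.csv`,
`otutable_rhea.tab`) are this package's convention.

## Synthetic generators

All randomness flows through one explicitly seeded
`numpy.random.Generator`; identical parameters give bit-identical output.

**Community.** Per-feature totals are log-normal —
exp(Normal(log_mean = 6.0, log_sd = 1.5)), natural log, rounded, ≥ 1 —
giving a median of ≈ 400 reads with a heavy tail from a handful to tens
of thousands of reads, the canonical shape of microbial abundance
distributions. Each feature occupies a random subset of `home_samples`
samples (default 1, i.e. sample-exclusive), reads spread multinomially.

**Crosstalk injection.** Per feature, Binomial(C_i, γ) reads are drawn
without replacement from its current per-sample counts (removal
proportional to abundance) and redistributed uniformly over all samples,
possibly landing back home. Reads are moved, never created — per-feature
totals are conserved, matching the misassignment mechanism — and a mask
records entries turned from zero to positive.

**Concatenated pairs.** Per record, an overlap o is drawn uniformly from
`overlap_range`; a random template of length 2·read_len − o is cut into
its two read-length ends and joined with `spacer_len` (default 10) Ns.
Positive o ⇒ exactly mergeable back to the template; o ≤ 0 ⇒ a true gap
of −o unsequenced bases, not mergeable. A fixed template length is not a
free parameter: template length, read length and overlap are linked by
that identity, so the generator derives it per record.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: read-level errors and chimeras (records are
error-free consensus sequences), compositional correlation between taxa,
non-uniform (index- or lane-structured) hopping, variable sequencing
depth per sample, and PCR amplification bias. Results on real tables
depend on how well the uniform-leak assumption holds for the instrument
at hand.

## Problem sizes and determinism

The test suite and the acceptance script run at the sizes the properties
are stated for: 200 random tables ≤ 10×10 for oracle equivalence, 100
tables for the algebraic laws, 500 simulated pairs per merge scenario,
exhaustive octave checks for counts up to 2^16, and a 50-feature ×
12-sample end-to-end crosstalk recovery — all chosen so each check is
exact (100%-style properties rather than statistical tolerances).
CLI runs write no timestamps into output files, so reruns with the same
seed are byte-identical; logs (which do carry timestamps) go to stderr
only.

## Known limitations

* γ is a fixed input, not estimated from the data; a badly wrong γ
  shifts the flagging threshold proportionally.
* The crosstalk model is uniform across samples; structured hopping
  (e.g. between adjacent indices) is not modelled, and numeric parity
  with closed-source implementations of similar filters is not claimed.
* Overlap merging is exact-match-based on denoised sequences; it does
  not use base qualities and cannot detect chimeric joins.
* Trees are handled only as verbatim pass-through text to the R
  hand-off; no phylogenetic computation is performed.
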