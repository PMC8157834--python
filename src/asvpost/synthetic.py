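"""Deterministic generators of synthetic amplicon data for every stage.

Three generators mirror the statistical structure the toolkit assumes:

* :func:`simulate_community` — a features × samples count table whose
  per-feature totals are log-normal (the canonical heavy-tailed shape of
  microbial abundance distributions) and whose features live only in a
  small "home" subset of samples.
* :func:`inject_crosstalk` — demultiplexing misassignment: per feature,
  a binomial(C_i, γ) number of reads is moved out of its home samples
  and scattered uniformly over all samples.  Reads are moved, never
  created, so per-feature totals are conserved exactly; a boolean mask
  records the entries that leakage turned from zero to positive.
* :func:`simulate_concatenated_pairs` — N-spacer-concatenated ASVs with
  known overlap structure: each record is built from a random template
  whose two read-length ends overlap by a chosen amount (negative =
  a true sequencing gap), so merge behaviour is known by construction.

All randomness flows through one explicitly seeded
``numpy.random.Generator``; identical specs produce bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AsvpostError
from .io import AsvRecord, FeatureTable


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic community.

    Per-feature total read counts are drawn log-normally:
    ``exp(Normal(log_mean, log_sd))`` rounded to integers ≥ 1.  The
    defaults (log_mean 6.0, log_sd 1.5, natural log) give a median of
    about 400 reads per feature with a realistic heavy tail spanning
    tens to tens of thousands of reads.  Each feature is then assigned
    ``home_samples`` distinct home samples and its reads are spread over
    them multinomially; ``home_samples=1`` yields sample-exclusive
    communities, the cleanest ground truth for crosstalk experiments.
    """

    n_features: int
    n_samples: int
    seed: int
    log_mean: float = 6.0
    log_sd: float = 1.5
    home_samples: int = 1

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_samples < 1:
            raise AsvpostError("n_features and n_samples must be >= 1")
        if not 1 <= self.home_samples <= self.n_samples:
            raise AsvpostError("home_samples must be in [1, n_samples]")
        if self.log_sd < 0:
            raise AsvpostError("log_sd must be >= 0")


@dataclass(frozen=True)
class LeakGroundTruth:
    """A contaminated table with its clean original and injection mask.

    ``mask[i, j]`` is True where the clean count was zero and leakage
    made it positive.  Per-feature row totals are identical between the
    clean and contaminated tables.
    """

    contaminated: FeatureTable
    clean: FeatureTable
    mask: np.ndarray


def simulate_community(spec: SimulationSpec) -> FeatureTable:
    """Draw a synthetic community table according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    totals = np.maximum(
        1, np.rint(np.exp(rng.normal(spec.log_mean, spec.log_sd, spec.n_features)))
    ).astype(np.int64)
    counts = np.zeros((spec.n_features, spec.n_samples), dtype=np.int64)
    probs = np.full(spec.home_samples, 1.0 / spec.home_samples)
    for i in range(spec.n_features):
        homes = rng.choice(spec.n_samples, size=spec.home_samples, replace=False)
        counts[i, homes] = rng.multinomial(totals[i], probs)
    feature_ids = [f"ASV_{i + 1:04d}" for i in range(spec.n_features)]
    sample_ids = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    return FeatureTable.from_arrays(counts, feature_ids, sample_ids)


def inject_crosstalk(
    table: FeatureTable, gamma: float, seed: int
) -> LeakGroundTruth:
    """Move a binomial(C_i, γ) share of each feature's reads across samples.

    Reads to leak are drawn without replacement from the feature's
    current per-sample counts (so removal is proportional to abundance)
    and redistributed uniformly at random over all samples, possibly
    landing back home.  γ = 1 is rejected as degenerate.
    """
    if not 0.0 <= gamma < 1.0:
        raise AsvpostError(f"gamma must be in [0,1), got {gamma}")
    rng = np.random.default_rng(seed)
    clean = table.counts
    contaminated = clean.copy()
    n_samples = table.shape[1]
    uniform = np.full(n_samples, 1.0 / n_samples)
    for i in range(clean.shape[0]):
        total = int(clean[i].sum())
        leak = int(rng.binomial(total, gamma)) if total > 0 else 0
        if leak == 0:
            continue
        removed = rng.multivariate_hypergeometric(contaminated[i], leak)
        contaminated[i] -= removed
        contaminated[i] += rng.multinomial(leak, uniform)
    mask = (clean == 0) & (contaminated > 0)
    return LeakGroundTruth(
        contaminated=FeatureTable.from_arrays(
            contaminated, table.feature_ids, table.sample_ids
        ),
        clean=FeatureTable.from_arrays(clean, table.feature_ids, table.sample_ids),
        mask=mask,
    )


_BASES = np.array(list("ACGT"))


def simulate_concatenated_pairs(
    n: int,
    read_len: int = 150,
    overlap_range: tuple[int, int] = (12, 40),
    spacer_len: int = 10,
    seed: int = 0,
) -> tuple[list[AsvRecord], dict[str, str]]:
    """Build N-concatenated pair records with known overlap ground truth.

    For each record an overlap o is drawn uniformly from
    ``overlap_range`` (inclusive); the generating template has length
    2·read_len − o, and the record is the first and last ``read_len``
    bases joined by a run of ``spacer_len`` Ns.  Positive o means the
    fragments truly overlap and the record is exactly mergeable back to
    its template; o ≤ 0 means a true gap of −o unsequenced bases, so the
    record is not mergeable.  Returns the records and a mapping from
    record ID to its template.
    """
    if n < 1:
        raise AsvpostError("n must be >= 1")
    if read_len < 1 or spacer_len < 1:
        raise AsvpostError("read_len and spacer_len must be >= 1")
    lo, hi = overlap_range
    if lo > hi:
        raise AsvpostError(f"empty overlap_range {overlap_range}")
    if hi > read_len:
        raise AsvpostError("overlap cannot exceed read_len")
    rng = np.random.default_rng(seed)
    records: list[AsvRecord] = []
    templates: dict[str, str] = {}
    for i in range(n):
        overlap = int(rng.integers(lo, hi + 1))
        tlen = 2 * read_len - overlap
        template = "".join(rng.choice(_BASES, size=tlen))
        left = template[:read_len]
        right = template[tlen - read_len :]
        rid = f"PAIR_{i + 1:04d}"
        records.append(AsvRecord(id=rid, sequence=left + "N" * spacer_len + right))
        templates[rid] = template
    return records, templates
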