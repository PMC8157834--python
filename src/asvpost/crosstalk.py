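"""Between-sample crosstalk (index-hopping) removal from feature tables.

In multiplexed amplicon runs, demultiplexing errors let a small fraction
of a feature's reads "leak" into the wrong samples.  The leaked reads are
negligible for abundance estimates but inflate diversity: a feature
appears present, at low count, in samples it never occupied.

The model used here assumes leakage is uniform across samples.  For
feature *i* with total count C_i over N samples, a fraction γ of its
reads is expected to leak, giving a per-sample expected leak count

    e_i = γ · C_i / N.

Each positive entry x_ij is scored by how compatible it is with pure
leakage,

    s_ij = e_i / (e_i + x_ij)   ∈ (0, 1],

which is ½ when the observed count equals the expectation and decreases
monotonically as x_ij grows past it.  Entries with s_ij ≥ τ are flagged
and zeroed.  The default τ = 1/3 flags counts up to twice the expected
leak (x_ij ≤ 2·e_i).

Two guards protect genuine low-abundance features: rows with total below
``min_total`` are never touched, and a row whose flagged removals would
exceed ``max_row_loss`` of its total passes through unchanged (a feature
that is low but evenly spread everywhere looks like leakage yet removing
it wholesale would erase a real organism).  Flagged entries are zeroed,
never decremented: the goal is removing spurious presence, not abundance
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AsvpostError, ConsistencyError
from .io import FeatureTable


@dataclass(frozen=True)
class CrosstalkParams:
    """Parameters of the uniform-leak crosstalk filter.

    gamma
        Expected fraction of each feature's reads that leak uniformly
        across samples.  Default 0.01, the order of magnitude of reported
        index-hopping rates on patterned flow cells.
    tau
        Score threshold in (0, 1); an entry is flagged when
        s_ij = e_i/(e_i + x_ij) ≥ tau.  Default 1/3, i.e. flag counts
        within twofold of the expected leak.
    max_row_loss
        Maximum fraction of a feature's reads the filter may remove;
        above it the whole row is skipped (reported, never altered).
    min_total
        Features with total count below this are skipped.
    """

    gamma: float = 0.01
    tau: float = 1.0 / 3.0
    max_row_loss: float = 0.1
    min_total: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise AsvpostError(f"gamma must be in [0,1], got {self.gamma}")
        if not 0.0 < self.tau < 1.0:
            raise AsvpostError(f"tau must be in (0,1), got {self.tau}")
        if not 0.0 <= self.max_row_loss <= 1.0:
            raise AsvpostError(
                f"max_row_loss must be in [0,1], got {self.max_row_loss}"
            )
        if self.min_total < 0:
            raise AsvpostError(f"min_total must be >= 0, got {self.min_total}")


@dataclass(frozen=True)
class LeakProfile:
    """Per-feature expected leak under the uniform model: e_i = γ·C_i/N."""

    totals: np.ndarray       # C_i, per-feature total counts
    n_samples: int           # N
    gamma: float
    expected_leak: np.ndarray  # e_i

    @property
    def n_features(self) -> int:
        return self.totals.shape[0]


@dataclass
class CrosstalkReport:
    """What the filter did: totals removed and per-feature skip reasons."""

    entries_zeroed: int = 0
    reads_removed: int = 0
    skipped: dict[str, str] = field(default_factory=dict)
    scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "entries_zeroed": self.entries_zeroed,
            "reads_removed": self.reads_removed,
            "n_features_skipped": len(self.skipped),
            "skipped": self.skipped,
        }


def leak_profile(table: FeatureTable, gamma: float) -> LeakProfile:
    """Compute per-feature expected leak counts e_i = γ·C_i/N."""
    if not 0.0 <= gamma <= 1.0:
        raise AsvpostError(f"gamma must be in [0,1], got {gamma}")
    n_features, n_samples = table.shape
    if n_samples == 0:
        raise AsvpostError("feature table has no samples")
    totals = table.counts.sum(axis=1)
    expected = gamma * totals.astype(np.float64) / n_samples
    return LeakProfile(
        totals=totals, n_samples=n_samples, gamma=gamma, expected_leak=expected
    )


def crosstalk_scores(table: FeatureTable, profile: LeakProfile) -> np.ndarray:
    """Score every entry: s_ij = e_i/(e_i + x_ij) for x_ij > 0, else 0.

    Larger scores mean more crosstalk-like.  For fixed e_i > 0 the score
    is strictly decreasing in the observed count.
    """
    x = table.counts
    if x.shape[0] != profile.n_features or x.shape[1] != profile.n_samples:
        raise ConsistencyError(
            f"profile shape ({profile.n_features} x {profile.n_samples}) does "
            f"not match table shape {x.shape}"
        )
    e = profile.expected_leak[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(x > 0, e / (e + x), 0.0)
    # e_i = 0 rows: 0/(0+x) is 0 already for x > 0; NaN cannot occur since
    # the x == 0 branch is masked out.
    return s


def remove_crosstalk(
    table: FeatureTable,
    params: CrosstalkParams | None = None,
    keep_scores: bool = False,
) -> tuple[FeatureTable, CrosstalkReport]:
    """Zero out entries attributable to crosstalk; never alters skipped rows.

    An entry is zeroed iff it is positive, its score reaches ``tau`` and
    its feature is not protected by a guard.  Returns the filtered table
    and a report; the input table is left untouched.
    """
    if params is None:
        params = CrosstalkParams()
    profile = leak_profile(table, params.gamma)
    scores = crosstalk_scores(table, profile)
    x = table.counts  # already a copy

    flagged = (x > 0) & (scores >= params.tau)
    flagged_loss = np.where(flagged, x, 0).sum(axis=1)
    totals = profile.totals

    low_total = totals < params.min_total
    over_loss = flagged_loss > params.max_row_loss * totals
    has_flags = flagged.any(axis=1)
    skip = has_flags & (low_total | over_loss)

    report = CrosstalkReport(scores=scores if keep_scores else None)
    feature_ids = table.feature_ids
    for i in np.flatnonzero(skip):
        reason = (
            f"total {totals[i]} < min_total {params.min_total}"
            if low_total[i]
            else (
                f"flagged removal {flagged_loss[i]} exceeds "
                f"max_row_loss {params.max_row_loss} of total {totals[i]}"
            )
        )
        report.skipped[feature_ids[i]] = reason

    zero = flagged & ~skip[:, None]
    out = x.copy()
    out[zero] = 0
    report.entries_zeroed = int(zero.sum())
    report.reads_removed = int(x.sum() - out.sum())
    filtered = FeatureTable.from_arrays(out, feature_ids, table.sample_ids)
    return filtered, report
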