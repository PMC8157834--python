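"""Post-denoising resolution of N-concatenated variable-length amplicons.

Markers with highly variable amplicon length (the fungal ITS above all)
produce read pairs that may or may not overlap.  Denoising such runs
without joining the pairs yields ASVs of the form

    <forward fragment> NNNNNNNNNN <reverse fragment>

where the N run is an artificial spacer.  This module splits those
records, merges the pairs that actually overlap, keeps the truly
non-overlapping ones concatenated, and collapses features whose resolved
sequences coincide — summing their counts so per-sample totals are
exactly conserved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AsvpostError
from .io import AsvRecord, Dataset, FeatureTable

logger = logging.getLogger(__name__)

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class MergePolicy:
    """Knobs governing spacer detection and overlap acceptance.

    spacer_min_run
        Minimum run of Ns treated as a concatenation spacer (default 5;
        DADA2 emits 10, tolerating ≥5 is robust to upstream trimming,
        while isolated ambiguity Ns never split a sequence).
    min_overlap
        Shortest suffix/prefix overlap accepted when merging (default 12).
    max_mismatch_fraction
        Mismatches tolerated inside an overlap of length L, as a fraction
        (accept when mismatches ≤ floor(fraction·L)).  Default 0: denoised
        ASVs are consensus sequences, so true overlaps should be exact.
    """

    spacer_min_run: int = 5
    min_overlap: int = 12
    max_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.spacer_min_run < 1:
            raise AsvpostError("spacer_min_run must be >= 1")
        if self.min_overlap < 1:
            raise AsvpostError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise AsvpostError("max_mismatch_fraction must be in [0,1]")


@dataclass(frozen=True)
class SplitPair:
    """The two N-free fragments flanking a spacer run."""

    left: str
    right: str
    spacer_len: int


@dataclass
class MergeReport:
    """Per-run outcome tally; outcomes lists (feature_id, outcome) pairs.

    Invariant: n_merged + n_kept_concatenated + n_passthrough equals the
    number of input features.
    """

    n_merged: int = 0
    n_kept_concatenated: int = 0
    n_passthrough: int = 0
    n_collapsed: int = 0
    outcomes: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_merged": self.n_merged,
            "n_kept_concatenated": self.n_kept_concatenated,
            "n_passthrough": self.n_passthrough,
            "n_collapsed": self.n_collapsed,
            "outcomes": [list(t) for t in self.outcomes],
        }


def split_concatenated(seq: str, spacer_min_run: int = 5) -> Optional[SplitPair]:
    """Split a sequence at its N spacer, or return None if not splittable.

    Splittable means: exactly one maximal run of ≥ ``spacer_min_run`` Ns,
    strictly internal, with both flanking fragments free of Ns.  Two or
    more qualifying runs are ambiguous (warned, not split); shorter runs
    are treated as ordinary ambiguity calls.
    """
    runs = [m for m in _N_RUN.finditer(seq) if m.end() - m.start() >= spacer_min_run]
    if len(runs) == 0:
        return None
    if len(runs) > 1:
        logger.warning(
            "sequence has %d candidate spacer runs; ambiguous, not splitting",
            len(runs),
        )
        return None
    run = runs[0]
    if run.start() == 0 or run.end() == len(seq):
        return None
    left, right = seq[: run.start()], seq[run.end() :]
    if "N" in left or "N" in right:
        logger.warning("fragments flanking the spacer contain Ns; not splitting")
        return None
    return SplitPair(left=left, right=right, spacer_len=run.end() - run.start())


def overlap_merge(pair: SplitPair, policy: MergePolicy | None = None) -> Optional[str]:
    """Merge a split pair by its longest acceptable suffix/prefix overlap.

    Candidate overlap lengths L run from min(|left|, |right|) down to
    ``min_overlap``; the length-L suffix of the left fragment is aligned
    with the length-L prefix of the right one, and the first (longest) L
    whose mismatch count is within policy is accepted, returning
    ``left + right[L:]`` (|merged| = |left| + |right| − L; at mismatching
    positions the left, forward-read-derived base is kept).  Returns None
    when no overlap qualifies.
    """
    if policy is None:
        policy = MergePolicy()
    left, right = pair.left, pair.right
    for length in range(min(len(left), len(right)), policy.min_overlap - 1, -1):
        mismatches = sum(
            a != b for a, b in zip(left[len(left) - length :], right[:length])
        )
        if mismatches <= int(policy.max_mismatch_fraction * length):
            return left + right[length:]
    return None


def merge_features(
    ds: Dataset, policy: MergePolicy | None = None
) -> tuple[Dataset, MergeReport]:
    """Resolve every N-concatenated feature of a dataset and collapse duplicates.

    Each feature's sequence is replaced by its merge result when the pair
    overlaps, kept concatenated otherwise; sequences without a spacer pass
    through untouched.  Features whose final sequences are identical are
    collapsed into one feature whose counts are the elementwise sum, so
    per-sample column totals are exactly conserved.  The collapsed feature
    keeps the ID of the member with the largest total count (ties: first
    in input order) and that member's taxonomy row.
    """
    if policy is None:
        policy = MergePolicy()
    if ds.sequences is None:
        raise AsvpostError("merge_features requires a dataset with sequences")
    ds.validate()

    report = MergeReport()
    seq_of = ds.sequence_map()
    final_seqs: dict[str, str] = {}
    for fid in ds.table.feature_ids:
        seq = seq_of[fid]
        pair = split_concatenated(seq, policy.spacer_min_run)
        if pair is None:
            report.n_passthrough += 1
            report.outcomes.append((fid, "passthrough"))
            final_seqs[fid] = seq
            continue
        merged = overlap_merge(pair, policy)
        if merged is None:
            report.n_kept_concatenated += 1
            report.outcomes.append((fid, "kept_concatenated"))
            final_seqs[fid] = seq
        else:
            report.n_merged += 1
            report.outcomes.append((fid, "merged"))
            final_seqs[fid] = merged

    # group features by final sequence, preserving first-occurrence order
    groups: dict[str, list[str]] = {}
    for fid in ds.table.feature_ids:
        groups.setdefault(final_seqs[fid], []).append(fid)

    frame = ds.table.frame
    totals = frame.sum(axis=1)
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    for seq, members in groups.items():
        best = max(members, key=lambda f: (totals[f], -members.index(f)))
        kept_ids.append(best)
        rows.append(frame.loc[members].to_numpy().sum(axis=0))
    report.n_collapsed = len(ds.table.feature_ids) - len(kept_ids)

    new_table = FeatureTable.from_arrays(
        np.vstack(rows) if rows else np.zeros((0, ds.table.shape[1]), dtype=np.int64),
        kept_ids,
        ds.table.sample_ids,
    )
    new_sequences = [
        AsvRecord(id=fid, sequence=seq) for seq, fid in zip(groups.keys(), kept_ids)
    ]
    new_taxonomy = ds.taxonomy.loc[kept_ids] if ds.taxonomy is not None else None
    out = Dataset(
        table=new_table,
        sequences=new_sequences,
        taxonomy=new_taxonomy,
        metadata=ds.metadata,
    ).validate()
    return out, report
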