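"""Octave plots: per-sample histograms of feature abundances in log2 bins.

A feature with count c ≥ 1 in a sample falls in bin k = floor(log2 c),
i.e. counts in [2^k, 2^(k+1)) share a bin; zero counts are excluded.
Binning is exact integer arithmetic (bit length), never floating point.
The shape of these histograms is a quick quality check on an amplicon
run — e.g. a sample whose mass sits entirely in the lowest octaves is a
candidate for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import FeatureTable


def octave_bin(count: int) -> int:
    """Exact floor(log2 count) for count ≥ 1, via bit length."""
    if count < 1:
        raise ValueError(f"octave bin undefined for count {count}")
    return int(count).bit_length() - 1


@dataclass(frozen=True)
class OctaveHistogram:
    """Mapping bin k → number of features with count in [2^k, 2^(k+1))."""

    sample_id: str
    bins: dict[int, int]

    @property
    def n_features(self) -> int:
        return sum(self.bins.values())


def octave_histogram(table: FeatureTable, sample_id: str) -> OctaveHistogram:
    """Histogram of one sample's nonzero feature counts in octave bins."""
    counts = table.sample_counts(sample_id)  # raises KeyError if unknown
    bins: dict[int, int] = {}
    for c in counts.to_numpy():
        if c > 0:
            k = octave_bin(int(c))
            bins[k] = bins.get(k, 0) + 1
    return OctaveHistogram(sample_id=sample_id, bins=dict(sorted(bins.items())))


def octave_summary(
    table: FeatureTable,
) -> tuple[list[OctaveHistogram], pd.DataFrame]:
    """All per-sample histograms plus a tidy long-format frame.

    The frame has one row per (sample, bin) with the bin edges spelled
    out: low_edge = 2^k, high_edge = 2^(k+1) − 1, n_features.  Rows are
    sorted by sample (table order) then bin.
    """
    histograms = [octave_histogram(table, s) for s in table.sample_ids]
    rows = [
        {
            "sample": h.sample_id,
            "bin": k,
            "low_edge": 2**k,
            "high_edge": 2 ** (k + 1) - 1,
            "n_features": n,
        }
        for h in histograms
        for k, n in h.bins.items()
    ]
    tidy = pd.DataFrame(
        rows, columns=["sample", "bin", "low_edge", "high_edge", "n_features"]
    )
    return histograms, tidy


def write_octave_tsv(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _, tidy = octave_summary(table)
    tidy.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def plot_octave(hist: OctaveHistogram, path: str | Path) -> Path:
    """Best-effort bar chart of one sample's octave histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ks = sorted(hist.bins)
    ax.bar(ks, [hist.bins[k] for k in ks], width=0.9, color="#4878a8")
    ax.set_xlabel("abundance octave (floor log2 count)")
    ax.set_ylabel("features")
    ax.set_title(hist.sample_id)
    if ks:
        ax.set_xticks(ks)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
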