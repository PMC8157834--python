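"""Bit-exact input bundles for MicrobiomeAnalyst and Rhea.

Both downstream tools are picky about their input dialects, and silent
drift there turns into cryptic upload failures, so the sentinels are
pinned byte-exact:

* MicrobiomeAnalyst — comma-separated; abundance and metadata files open
  with ``#NAME``, the taxonomy file with ``#TAXONOMY`` followed by the
  seven canonical ranks.
* Rhea — a single tab-separated OTU table opening with ``#OTUId``, with
  an optional trailing ``taxonomy`` column holding the ``;``-joined
  lineage.

Exports never alter counts: re-parsing any abundance file reproduces the
source matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import AsvpostError, DataFormatError
from .io import RANKS, Dataset

MICROBIOMEANALYST = "microbiomeanalyst"
RHEA = "rhea"


@dataclass(frozen=True)
class ExportBundle:
    """Record of an export: target tool, (role, path) pairs, lineage join."""

    target: str
    files: tuple[tuple[str, Path], ...]
    lineage_delimiter: str

    def path(self, role: str) -> Path:
        for r, p in self.files:
            if r == role:
                return p
        raise KeyError(role)


def _require_samples(ds: Dataset) -> None:
    if ds.table.shape[1] == 0:
        raise AsvpostError("cannot export a table with no samples")


def _lineage_frame(ds: Dataset) -> pd.DataFrame:
    """Taxonomy aligned to table feature order, padded/truncated to 7 ranks."""
    tax = ds.taxonomy.reindex(ds.table.feature_ids).fillna("")
    out = pd.DataFrame("", index=tax.index, columns=list(RANKS), dtype=str)
    ncol = min(len(RANKS), tax.shape[1])
    out.iloc[:, :ncol] = tax.iloc[:, :ncol].astype(str).to_numpy()
    return out


def export_microbiomeanalyst(ds: Dataset, outdir: str | Path) -> ExportBundle:
    """Write abundance/taxonomy/metadata CSVs in MicrobiomeAnalyst dialect.

    Feature and sample order are preserved; taxonomy and metadata files
    are written only when those components are present.  Names containing
    a comma are quoted (standard CSV quoting).
    """
    _require_samples(ds)
    ds.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    files: list[tuple[str, Path]] = []
    abundance = outdir / "abundance.csv"
    ds.table.frame.to_csv(abundance, index_label="#NAME", lineterminator="\n")
    files.append(("abundance", abundance))

    if ds.taxonomy is not None:
        taxonomy = outdir / "taxonomy.csv"
        _lineage_frame(ds).to_csv(
            taxonomy, index_label="#TAXONOMY", lineterminator="\n"
        )
        files.append(("taxonomy", taxonomy))

    if ds.metadata is not None:
        metadata = outdir / "metadata.csv"
        ds.metadata.reindex(ds.table.sample_ids).to_csv(
            metadata, index_label="#NAME", lineterminator="\n"
        )
        files.append(("metadata", metadata))

    return ExportBundle(
        target=MICROBIOMEANALYST, files=tuple(files), lineage_delimiter=";"
    )


def export_rhea(ds: Dataset, outpath: str | Path) -> ExportBundle:
    """Write the single tab-separated OTU table Rhea expects.

    Header starts with ``#OTUId``; when taxonomy is present a final
    ``taxonomy`` column holds each feature's lineage joined with ``;``.
    Rhea has no quoting convention, so IDs containing the tab delimiter
    are rejected outright.
    """
    _require_samples(ds)
    ds.validate()
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)

    bad = [
        name
        for name in ds.table.feature_ids + ds.table.sample_ids
        if "\t" in name or "\n" in name
    ]
    if bad:
        raise DataFormatError(
            f"IDs containing tab/newline cannot be exported for Rhea: {bad}"
        )

    frame = ds.table.frame.copy()
    if ds.taxonomy is not None:
        lineage = _lineage_frame(ds)
        frame["taxonomy"] = [";".join(row) for row in lineage.to_numpy()]
    frame.to_csv(outpath, sep="\t", index_label="#OTUId", lineterminator="\n")
    return ExportBundle(
        target=RHEA, files=(("otu_table", outpath),), lineage_delimiter=";"
    )
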