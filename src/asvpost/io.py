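"""Reading and writing the core amplicon artifacts as one coherent dataset.

The central object is the feature table: a features × samples matrix of
non-negative integer read counts, as produced by a denoiser such as DADA2.
Alongside it live the representative ASV sequences (FASTA), an optional
ranked taxonomy table and optional per-sample metadata.  Loading
cross-validates the components so that downstream stages can assume their
IDs agree.

Conventions
-----------
* Tables are stored features-as-rows, samples-as-columns.  A
  ``samples_as_rows`` flag transposes on load for tables exported the
  other way around.
* The first header cell of a table carries no information and is ignored
  on read (``""``, ``"#OTU ID"``, ``"#NAME"`` ... all accepted); on write
  we emit ``"#OTU ID"``.
* Sequences are uppercased on load; IUPAC ambiguity codes other than N
  are mapped to N with a warning, because only N is meaningful to the
  pair-merging stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, DataFormatError

logger = logging.getLogger(__name__)

#: Canonical rank names for a 7-rank lineage, DADA2/DECIPHER style.
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class AsvRecord:
    """A representative sequence: feature ID plus DNA over {A,C,G,T,N}.

    A run of Ns inside the sequence may mark an unmerged read pair that
    was concatenated with a spacer by the denoiser.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataFormatError("AsvRecord ID must be non-empty")
        if not self.sequence:
            raise DataFormatError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise DataFormatError(
                f"sequence for {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )


class FeatureTable:
    """Features × samples matrix of non-negative integer read counts.

    Thin wrapper around a pandas DataFrame that enforces the invariants
    every stage relies on: integer counts ≥ 0, unique non-empty feature
    and sample IDs, and at least one sample.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 1:
            raise DataFormatError("feature table must have at least 1 sample")
        index = frame.index.astype(str)
        columns = frame.columns.astype(str)
        if index.has_duplicates:
            dups = index[index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate feature IDs: {dups}")
        if columns.has_duplicates:
            dups = columns[columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample IDs: {dups}")
        if (index == "").any() or (columns == "").any():
            raise DataFormatError("feature/sample IDs must be non-empty strings")
        values = _coerce_counts(frame)
        self._frame = pd.DataFrame(values, index=index, columns=columns)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "FeatureTable":
        return cls(
            pd.DataFrame(
                np.asarray(counts), index=list(feature_ids), columns=list(sample_ids)
            )
        )

    # -- accessors -----------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (int64; do not mutate in place)."""
        return self._frame

    @property
    def counts(self) -> np.ndarray:
        """Count matrix as an int64 ndarray copy, shape (n_features, n_samples)."""
        return self._frame.to_numpy(copy=True)

    @property
    def feature_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def sample_counts(self, sample_id: str) -> pd.Series:
        if sample_id not in self._frame.columns:
            raise KeyError(f"unknown sample ID: {sample_id!r}")
        return self._frame[sample_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        f, s = self.shape
        return f"FeatureTable({f} features x {s} samples)"


def _coerce_counts(frame: pd.DataFrame) -> np.ndarray:
    """Validate and convert a raw table to int64, naming offenders."""
    out = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        series = frame.iloc[:, j]
        try:
            numeric = pd.to_numeric(series)
        except (ValueError, TypeError) as exc:
            raise DataFormatError(
                f"non-numeric count in column {col!r}: {exc}"
            ) from exc
        arr = np.asarray(numeric)
        frac = arr != np.floor(arr)
        if frac.any():
            row = frame.index[int(np.argmax(frac))]
            raise DataFormatError(
                f"non-integer count at feature {row!r}, sample {col!r}"
            )
        if (arr < 0).any():
            row = frame.index[int(np.argmax(arr < 0))]
            raise DataFormatError(
                f"negative count at feature {row!r}, sample {col!r}"
            )
        out[:, j] = arr.astype(np.int64)
    return out


@dataclass
class Dataset:
    """A feature table with optional sequences, taxonomy and metadata.

    ``taxonomy`` is a DataFrame indexed by feature ID with one column per
    rank (empty string = unassigned); ``metadata`` is indexed by sample ID.
    ``validate()`` enforces cross-component ID consistency.
    """

    table: FeatureTable
    sequences: Optional[list[AsvRecord]] = None
    taxonomy: Optional[pd.DataFrame] = None
    metadata: Optional[pd.DataFrame] = None

    def validate(self) -> "Dataset":
        if self.sequences is not None:
            seq_ids = [r.id for r in self.sequences]
            if len(set(seq_ids)) != len(seq_ids):
                dups = sorted({s for s in seq_ids if seq_ids.count(s) > 1})
                raise DataFormatError(f"duplicate FASTA IDs: {dups}")
            if set(seq_ids) != set(self.table.feature_ids):
                extra = sorted(set(seq_ids) - set(self.table.feature_ids))
                missing = sorted(set(self.table.feature_ids) - set(seq_ids))
                raise ConsistencyError(
                    "FASTA/table feature ID mismatch: "
                    f"only in FASTA {extra}, only in table {missing}"
                )
        if self.taxonomy is not None:
            missing = sorted(
                set(self.table.feature_ids) - set(self.taxonomy.index.astype(str))
            )
            if missing:
                raise ConsistencyError(
                    f"features without a taxonomy row: {missing}"
                )
        if self.metadata is not None:
            missing = sorted(
                set(self.table.sample_ids) - set(self.metadata.index.astype(str))
            )
            if missing:
                raise ConsistencyError(
                    f"samples without a metadata row: {missing}"
                )
        return self

    def sequence_map(self) -> dict[str, str]:
        if self.sequences is None:
            raise ConsistencyError("dataset has no sequences")
        return {r.id: r.sequence for r in self.sequences}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


def load_table(
    path: str | Path, dialect: str = "tsv", samples_as_rows: bool = False
) -> FeatureTable:
    """Read a count table; first column = feature IDs, header = sample IDs."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=object)
    raw.index = raw.index.astype(str)
    if samples_as_rows:
        raw = raw.T
    return FeatureTable(raw)


def load_fasta(path: str | Path) -> list[AsvRecord]:
    """Read ASV sequences; uppercase and map non-ACGTN symbols to N."""
    records: list[AsvRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        mapped = _NON_ACGTN.sub("N", seq)
        if mapped != seq:
            logger.warning(
                "sequence %s: %d ambiguity character(s) mapped to N",
                rec.id,
                sum(a != b for a, b in zip(seq, mapped)),
            )
        if rec.id in seen:
            raise DataFormatError(f"duplicate FASTA IDs: [{rec.id!r}]")
        seen.add(rec.id)
        records.append(AsvRecord(id=rec.id, sequence=mapped))
    return records


def load_taxonomy(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a ranked taxonomy table: first column feature ID, then ranks."""
    tax = pd.read_csv(
        Path(path), sep=_sep(dialect), index_col=0, dtype=str, keep_default_na=False
    )
    tax.index = tax.index.astype(str)
    if tax.index.has_duplicates:
        dups = tax.index[tax.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate taxonomy feature IDs: {dups}")
    return tax


def load_metadata(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    meta = pd.read_csv(
        Path(path), sep=_sep(dialect), index_col=0, dtype=str, keep_default_na=False
    )
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate metadata sample IDs: {dups}")
    if meta.columns.has_duplicates:
        raise DataFormatError("duplicate metadata column names")
    return meta


def load_dataset(
    table_path: str | Path,
    fasta_path: Optional[str | Path] = None,
    taxonomy_path: Optional[str | Path] = None,
    metadata_path: Optional[str | Path] = None,
    dialect: str = "tsv",
    samples_as_rows: bool = False,
) -> Dataset:
    """Load and cross-validate a feature table with its companions."""
    table = load_table(table_path, dialect=dialect, samples_as_rows=samples_as_rows)
    sequences = load_fasta(fasta_path) if fasta_path is not None else None
    taxonomy = (
        load_taxonomy(taxonomy_path, dialect=dialect)
        if taxonomy_path is not None
        else None
    )
    metadata = (
        load_metadata(metadata_path, dialect=dialect)
        if metadata_path is not None
        else None
    )
    return Dataset(
        table=table, sequences=sequences, taxonomy=taxonomy, metadata=metadata
    ).validate()


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def save_table(
    table: FeatureTable, path: str | Path, dialect: str = "tsv"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, sep=_sep(dialect), index_label="#OTU ID", lineterminator="\n")
    return path


def save_fasta(records: Sequence[AsvRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", newline="\n") as handle:
        SeqIO.write(seqrecs, handle, "fasta")  # wraps at 60 columns
    return path


def save_dataset(
    ds: Dataset, outdir: str | Path, dialect: str = "tsv"
) -> list[Path]:
    """Write every present component; returns the written paths.

    Round-trip law: ``load_dataset`` on the written files reproduces the
    dataset component-wise.
    """
    ds.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = dialect
    written = [save_table(ds.table, outdir / f"feature-table.{ext}", dialect)]
    if ds.sequences is not None:
        written.append(save_fasta(ds.sequences, outdir / "asvs.fasta"))
    if ds.taxonomy is not None:
        p = outdir / f"taxonomy.{ext}"
        ds.taxonomy.to_csv(p, sep=_sep(dialect), index_label="#OTU ID", lineterminator="\n")
        written.append(p)
    if ds.metadata is not None:
        p = outdir / f"metadata.{ext}"
        ds.metadata.to_csv(p, sep=_sep(dialect), index_label="#SampleID", lineterminator="\n")
        written.append(p)
    return written
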