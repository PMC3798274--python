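"""Validated tabular containers and TSV I/O.

All matrices share one layout: rows are samples (taxa, for reconstructed
content), columns are taxa or genomic elements, and the body is numeric.
TSV (tab-separated, UTF-8, mandatory header row, row ids in the first
column) is the primary interchange format, matching the table exports of
the large microbiome consortia.  Missing cells are treated as errors, not
zeros: silently zero-filling a count table would bias the downstream
regression.

BIOM reading is optional and requires the ``biom-format`` package; the
entry point exists but raises an informative error when the dependency is
absent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    MappingError,
    TableFormatError,
    TableValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonProfile",
    "ElementCounts",
    "ReferenceLengths",
    "ReferencePresence",
    "read_abundance_table",
    "read_reference_lengths",
    "read_reference_presence",
    "write_matrix",
    "align_samples",
    "convert_workbook",
]


def _validated_frame(df: pd.DataFrame, *, name: str, allow_negative: bool = False) -> pd.DataFrame:
    """Coerce to float and enforce the shared matrix invariants."""
    if df.index.has_duplicates:
        raise TableFormatError(f"{name}: duplicate row ids {sorted(df.index[df.index.duplicated()])}")
    if df.columns.has_duplicates:
        raise TableFormatError(f"{name}: duplicate column ids {sorted(df.columns[df.columns.duplicated()])}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"{name}: non-numeric cell ({exc})") from exc
    if np.isnan(values).any():
        raise TableValidationError(f"{name}: missing cells are errors, not zeros")
    if not allow_negative and (values < 0).any():
        raise TableValidationError(f"{name}: negative entries are not allowed")
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    return out


@dataclass(eq=False)
class _SampleMatrix:
    """Shared behaviour of the samples-by-features matrices."""

    data: pd.DataFrame

    _allow_negative = False

    def __post_init__(self) -> None:
        self.data = _validated_frame(
            self.data, name=type(self).__name__, allow_negative=self._allow_negative
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


class TaxonProfile(_SampleMatrix):
    """Per-sample taxon relative abundances (the regression design).

    Entries are dimensionless fractions g_ik >= 0.  Rows are not forced to
    sum to one at construction; use :func:`taxadecon.deconvolve.normalize_taxon_profile`
    before solving.
    """

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


class ElementCounts(_SampleMatrix):
    """Per-sample genomic-element read counts (the regression response).

    Counts may be fractional: annotation pipelines split tied read
    assignments into fractional counts.
    """

    @property
    def element_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(eq=False)
class ReferenceLengths:
    """Average ortholog length per element (nt), used for presence calling."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        s = self.lengths
        if s.index.has_duplicates:
            raise TableFormatError("ReferenceLengths: duplicate element ids")
        s = s.astype(float)
        if s.isna().any():
            raise TableValidationError("ReferenceLengths: missing lengths")
        if (s <= 0).any():
            bad = list(s.index[s <= 0])
            raise TableValidationError(f"ReferenceLengths: non-positive lengths for {bad}")
        self.lengths = pd.Series(s.to_numpy(), index=s.index.astype(str))

    def for_elements(self, element_ids) -> pd.Series:
        missing = [e for e in element_ids if e not in self.lengths.index]
        if missing:
            raise MappingError(f"no reference length for elements: {missing}")
        return self.lengths.loc[list(element_ids)]


@dataclass(eq=False)
class ReferencePresence:
    """Reference-genome element copy numbers with genus labels.

    An element counts as present in a genome when its (possibly fractional,
    strain-averaged) copy number is at least ``presence_cutoff`` — the
    conventional 0.1 floor used when annotating reference genomes.
    """

    copy_numbers: pd.DataFrame  # genomes x elements
    genus: pd.Series            # genome id -> genus label
    presence_cutoff: float = 0.1

    def __post_init__(self) -> None:
        self.copy_numbers = _validated_frame(self.copy_numbers, name="ReferencePresence")
        self.genus = self.genus.astype(str)
        self.genus.index = self.genus.index.astype(str)
        missing = [g for g in self.copy_numbers.index if g not in self.genus.index]
        if missing:
            raise TableValidationError(f"ReferencePresence: genomes without genus label: {missing}")
        if self.presence_cutoff <= 0:
            raise TableValidationError("ReferencePresence: presence_cutoff must be positive")
        self.genus = self.genus.loc[self.copy_numbers.index]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.copy_numbers.index)

    @property
    def element_ids(self) -> list[str]:
        return list(self.copy_numbers.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean genomes x elements presence matrix."""
        return self.copy_numbers >= self.presence_cutoff


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, comment=None)
    return df


def read_abundance_table(path, kind: str, format: str = "tsv"):
    """Read a samples x features table and validate it into a domain type.

    Parameters
    ----------
    path:
        File to read.
    kind:
        ``"taxon"`` for a relative-abundance table (:class:`TaxonProfile`)
        or ``"element"`` for a read-count table (:class:`ElementCounts`).
    format:
        ``"tsv"`` (default) or ``"biom"`` (requires the optional
        ``biom-format`` package).
    """
    if kind not in ("taxon", "element"):
        raise ValueError(f"kind must be 'taxon' or 'element', got {kind!r}")
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "biom":
        try:
            import biom  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise TableFormatError(
                "BIOM reading requires the optional 'biom-format' package"
            ) from exc
        table = biom.load_table(str(path))  # pragma: no cover
        df = table.to_dataframe(dense=True).T  # pragma: no cover
    else:
        raise ValueError(f"unknown format {format!r}")
    cls = TaxonProfile if kind == "taxon" else ElementCounts
    return cls(df)


def read_reference_lengths(path) -> ReferenceLengths:
    """Read a two-column TSV of element id -> average ortholog length (nt)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.shape[1] != 1:
        raise TableFormatError("reference lengths must have exactly one value column")
    return ReferenceLengths(df.iloc[:, 0])


def read_reference_presence(path, genus_column: str = "genus") -> ReferencePresence:
    """Read a genomes x elements copy-number TSV with a genus label column."""
    df = _read_tsv(path)
    if genus_column not in df.columns:
        raise TableFormatError(f"reference presence table lacks a {genus_column!r} column")
    genus = df[genus_column].astype(str)
    copy = df.drop(columns=[genus_column])
    return ReferencePresence(copy_numbers=copy, genus=genus)


def write_matrix(matrix, path) -> None:
    """Write any of the package's matrix types (or a bare DataFrame) as TSV.

    Floats use full ``%.10g`` precision so a read/write round trip is
    lossless to well below 1e-9.  Boolean presence calls are written as 0/1.
    """
    df = getattr(matrix, "data", None)
    if df is None:
        df = getattr(matrix, "calls", None)
    if df is None and isinstance(matrix, pd.DataFrame):
        df = matrix
    if df is None:
        raise TypeError(f"cannot write object of type {type(matrix).__name__}")
    if df.dtypes.apply(lambda d: d == bool).all() and df.shape[1] > 0:
        df = df.astype(int)
    df.to_csv(path, sep="\t", float_format="%.10g")


def align_samples(profile: TaxonProfile, counts: ElementCounts) -> tuple[TaxonProfile, ElementCounts]:
    """Align a taxon profile and a count table on their shared sample ids.

    Order-insensitive: samples are matched by id and returned in the
    profile's order (restricted to the overlap).  Raises when the id sets
    do not overlap.
    """
    common = [s for s in profile.sample_ids if s in set(counts.sample_ids)]
    if not common:
        raise AlignmentError("taxon profile and element counts share no sample ids")
    dropped = (set(profile.sample_ids) | set(counts.sample_ids)) - set(common)
    if dropped:
        logger.warning("align_samples: dropping %d unmatched samples: %s", len(dropped), sorted(dropped))
    return TaxonProfile(profile.data.loc[common]), ElementCounts(counts.data.loc[common])


def convert_workbook(path, out_dir) -> dict[str, Path]:
    """One-shot converter: each sheet of an .xlsx workbook becomes a TSV.

    Sheet headers are introspected rather than assumed: the first row is the
    header and the first column the row ids.  Returns the sheet -> file
    mapping, which is also logged.  Legacy binary .xls files need the
    ``xlrd`` package and are not supported here; re-save them as .xlsx.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(path, sheet_name=None, index_col=0, engine="openpyxl")
    mapping: dict[str, Path] = {}
    for sheet, df in sheets.items():
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in sheet)
        target = out_dir / f"{safe}.tsv"
        df.to_csv(target, sep="\t", float_format="%.10g")
        mapping[sheet] = target
        logger.info("convert_workbook: sheet %r -> %s", sheet, target)
    return mapping
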