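"""Readers and writers for beta matrices, probe annotations and genotype calls.

Beta matrices are probes x samples tables of methylation fractions in [0, 1]
with missing entries allowed. Two dialects are supported: plain TSV (first
column probe IDs, header row sample IDs) and GEO series-matrix files, where
the numeric table is delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` marker lines.

Missing tokens accepted on read: the empty string, ``NA`` and ``NaN``
(case-insensitive). Genomic coordinates are 1-based, fully closed, Build 37.
Probe and sample identifiers are opaque strings; no normalization is applied.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    BetaDomainError,
    BetaParseError,
    MatrixFormatError,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"", "na", "nan"})

GENOTYPE_ALPHABET = ("CC", "CD", "DD")

_SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
_SERIES_MATRIX_END = "!series_matrix_table_end"


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1]; NaN marks missing.

    Wraps a float :class:`pandas.DataFrame` whose index holds probe IDs and
    whose columns hold sample IDs, preserving input order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate probe IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample IDs: {dups[:5]}")
        self.data = self.data.astype(float, copy=False)
        values = self.data.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaDomainError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Raw float ndarray (probes x samples), NaN for missing."""
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe genomic metadata on Genome Build 37.

    ``cpg_offset`` is the 0-based index of the assayed CpG's cytosine within
    ``source_sequence``; the invariant ``source_sequence[cpg_offset:cpg_offset+2]
    == "CG"`` is enforced at construction.
    """

    probe_id: str
    chromosome: str
    position_bp: int
    source_sequence: str
    cpg_offset: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise AnnotationError(
                f"probe {self.probe_id}: position_bp must be >= 1 "
                f"(got {self.position_bp})"
            )
        seq = self.source_sequence
        off = self.cpg_offset
        if off < 0 or off + 1 >= len(seq) or seq[off : off + 2] != "CG":
            raise AnnotationError(
                f"probe {self.probe_id}: source sequence lacks CG at offset {off}"
            )


@dataclass
class GenotypeCallMatrix:
    """Probes x samples categorical calls from {CC, CD, DD}; NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise MatrixFormatError("duplicate probe or sample IDs in call matrix")
        flat = self.data.to_numpy(dtype=object).ravel()
        for v in flat:
            if v in GENOTYPE_ALPHABET:
                continue
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            raise MatrixFormatError(f"invalid genotype call {v!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def _case_variants(token: str) -> set[str]:
    from itertools import product

    return {
        "".join(chars)
        for chars in product(*((c.lower(), c.upper()) for c in token))
    }


# every case variant of the accepted missing tokens (read_csv matches exactly)
_NA_TOKENS = sorted({""} | _case_variants("na") | _case_variants("nan"))


def _parse_beta_table(source, **read_kwargs) -> BetaMatrix:
    """Parse a probe x sample numeric table from a path or file-like."""
    try:
        frame = pd.read_csv(
            source,
            sep="\t",
            index_col=0,
            na_values=_NA_TOKENS,
            keep_default_na=False,
            skip_blank_lines=True,
            **read_kwargs,
        )
    except pd.errors.EmptyDataError:
        raise MatrixFormatError("empty beta table") from None
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"malformed beta table: {exc}") from None
    if frame.shape[1] == 0:
        raise MatrixFormatError("header row contains no sample IDs")
    frame.index = pd.Index(
        [str(v).strip() for v in frame.index], name="probe_id"
    )
    frame.columns = [str(c).strip() for c in frame.columns]
    for column in frame.columns:
        if frame[column].dtype == object:
            coerced = pd.to_numeric(frame[column], errors="coerce")
            bad = coerced.isna() & frame[column].notna()
            if bad.any():
                probe = frame.index[int(np.argmax(bad.to_numpy()))]
                token = frame.loc[probe, column]
                raise BetaParseError(
                    f"non-numeric value {token!r} at probe {probe!r}, "
                    f"sample {column!r}"
                )
            frame[column] = coerced
    return BetaMatrix(frame)


def read_beta_matrix(path: str | Path, format: str = "tsv") -> BetaMatrix:
    """Read a beta matrix from a TSV or GEO series-matrix text file.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"tsv"`` (header row of sample IDs, first column of probe IDs) or
        ``"geo_series_matrix"``/``"geo"`` (the numeric table between the
        series-matrix begin/end marker lines is parsed).

    Raises
    ------
    BetaParseError
        On a non-numeric cell that is not a recognized missing token.
    BetaDomainError
        On a value outside [0, 1].
    MatrixFormatError
        On duplicate probe IDs or structural problems.
    """
    path = Path(path)
    if format in ("geo", "geo_series_matrix"):
        # locate the table region first, then let the C engine stream it
        begin = end = None
        with open(path, "r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle):
                marker = line.strip().lower()
                if marker == _SERIES_MATRIX_BEGIN:
                    begin = lineno
                elif marker == _SERIES_MATRIX_END:
                    end = lineno
                    break
        if begin is None or end is None or end - begin < 2:
            raise MatrixFormatError(
                f"{path}: no series-matrix table markers found"
            )
        return _parse_beta_table(
            path, skiprows=begin + 1, nrows=end - begin - 2
        )
    if format == "tsv":
        return _parse_beta_table(path)
    raise ValueError(f"unknown beta-matrix format {format!r}")


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as TSV with ``NA`` for missing entries."""
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def _derive_cpg_offset(probe_id: str, sequence: str) -> int:
    first = sequence.find("CG")
    if first < 0:
        raise AnnotationError(f"probe {probe_id}: source sequence contains no CG")
    if sequence.find("CG", first + 1) >= 0:
        warnings.warn(
            f"probe {probe_id}: multiple CG dinucleotides in source sequence; "
            "using the first (supply a cpg_offset column to disambiguate)",
            stacklevel=3,
        )
    return first


_ANNOTATION_COLUMN_ALIASES = {
    "probe_id": ("probe_id", "ilmnid", "id", "id_ref", "name", "probe"),
    "chromosome": ("chromosome", "chr", "chrom"),
    "position_bp": ("position_bp", "position", "pos", "mapinfo"),
    "source_sequence": ("source_sequence", "sequence", "sourceseq", "source_seq"),
    "cpg_offset": ("cpg_offset", "offset"),
}


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read a probe annotation table (CSV or TSV, sniffed from the header).

    Requires probe_id, chromosome, position and sequence columns (common
    aliases accepted). When no cpg_offset column is present the offset of the
    first ``CG`` in the source sequence is used, with a warning if the
    sequence contains more than one candidate.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    lower_map = {c.lower(): c for c in frame.columns}
    resolved: dict[str, str] = {}
    for canonical, aliases in _ANNOTATION_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower_map:
                resolved[canonical] = lower_map[alias]
                break
    required = ("probe_id", "chromosome", "position_bp", "source_sequence")
    missing = [c for c in required if c not in resolved]
    if missing:
        raise MatrixFormatError(
            f"{path}: annotation table missing columns {missing} "
            f"(found {list(frame.columns)})"
        )
    annotations: list[ProbeAnnotation] = []
    for _, row in frame.iterrows():
        probe_id = row[resolved["probe_id"]].strip()
        sequence = row[resolved["source_sequence"]].strip().upper()
        if "cpg_offset" in resolved and row[resolved["cpg_offset"]].strip():
            offset = int(row[resolved["cpg_offset"]])
        else:
            offset = _derive_cpg_offset(probe_id, sequence)
        annotations.append(
            ProbeAnnotation(
                probe_id=probe_id,
                chromosome=row[resolved["chromosome"]].strip(),
                position_bp=int(row[resolved["position_bp"]]),
                source_sequence=sequence,
                cpg_offset=offset,
            )
        )
    return annotations


def write_genotype_matrix(calls: GenotypeCallMatrix, path: str | Path) -> None:
    """Write calls as TSV: probes as rows, samples as columns, ``NA`` missing.

    Round-trips losslessly through :func:`read_genotype_matrix`.
    """
    if calls.data.empty:
        raise MatrixFormatError("refusing to write an empty call matrix")
    calls.data.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_genotype_matrix(path: str | Path) -> GenotypeCallMatrix:
    """Read a genotype call matrix written by :func:`write_genotype_matrix`."""
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    obj = frame.replace({t: np.nan for t in ("", "NA", "NaN", "nan", "na")})
    for v in obj.to_numpy(dtype=object).ravel():
        if isinstance(v, str) and v not in GENOTYPE_ALPHABET:
            raise MatrixFormatError(f"{path}: invalid genotype call {v!r}")
    return GenotypeCallMatrix(obj)


def genotype_matrix_from_arrays(
    probe_ids: Sequence[str],
    sample_ids: Sequence[str],
    calls: np.ndarray,
) -> GenotypeCallMatrix:
    """Build a call matrix from an object ndarray of {CC, CD, DD, NaN}."""
    frame = pd.DataFrame(
        calls, index=pd.Index(probe_ids, name="probe_id"), columns=list(sample_ids)
    )
    return GenotypeCallMatrix(frame)
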