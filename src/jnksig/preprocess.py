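"""Expression-matrix container, QC filters and normalisation.

Bulk RNA-seq from archival FFPE material is noisy: whole samples can fail
(too few reads mapped to the transcriptome) and many genes are detected in
only a fraction of samples.  This module provides the gene-by-sample
container used throughout the package and the standard cleanup applied
before any scoring or signature derivation:

1. drop samples whose total mapped-read count falls below a threshold
   (default 200,000 reads);
2. keep only genes expressed (count > 0) in at least 70% of the remaining
   samples;
3. log2 counts-per-million normalisation with a pseudocount;
4. per-gene z-scaling.

Filters are applied samples-first, then genes, which is the pipeline
default; the two orders are not interchangeable because the prevalence
denominator changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"
Z_SCORED = "z_scored"
_UNITS = (RAW_COUNTS, LOG_NORMALIZED, Z_SCORED)

#: column-sum threshold below which an FFPE sample is considered failed
DEFAULT_MIN_MAPPED_READS = 200_000
#: minimum fraction of samples in which a gene must be detected
DEFAULT_MIN_PREVALENCE = 0.70


class PreprocessError(ValueError):
    """Raised when a filter or normalisation contract is violated."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a units tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.
    units
        One of ``"raw_counts"``, ``"log_normalized"`` or ``"z_scored"``.
    """

    values: pd.DataFrame
    units: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise PreprocessError(f"unknown units {self.units!r}; expected one of {_UNITS}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PreprocessError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise PreprocessError(f"duplicate sample id {dup!r}")
        if self.values.size == 0:
            raise PreprocessError("empty expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise PreprocessError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise PreprocessError("expression values must be finite")
        if self.units == RAW_COUNTS and (arr < 0).any():
            raise PreprocessError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write as TSV with a ``#units=`` pragma line and gene ids in column 1."""
        with open(path, "w") as fh:
            fh.write(f"#units={self.units}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, units: str | None = None) -> "ExpressionMatrix":
        """Read a gene-by-sample TSV.

        The first line may be a ``#units=<tag>`` pragma; otherwise *units*
        must be supplied.  Ragged rows, duplicate ids, non-numeric cells and
        empty files are all rejected with explicit messages.
        """
        with open(path) as fh:
            first = fh.readline()
            pragma_units = None
            if first.startswith("#units="):
                pragma_units = first.strip().split("=", 1)[1]
                header_line = fh.readline()
            else:
                header_line = first
            if not header_line.strip():
                raise PreprocessError(f"{path}: empty expression file")
            header = header_line.rstrip("\n").split("\t")
            n_fields = len(header)
            rows, index = [], []
            for lineno, line in enumerate(fh, start=3 if pragma_units else 2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != n_fields:
                    raise PreprocessError(
                        f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_fields})"
                    )
                index.append(fields[0])
                try:
                    rows.append([float(x) for x in fields[1:]])
                except ValueError as exc:
                    raise PreprocessError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if not rows:
            raise PreprocessError(f"{path}: no data rows")
        df = pd.DataFrame(rows, index=index, columns=header[1:])
        resolved = units or pragma_units
        if resolved is None:
            raise PreprocessError(f"{path}: no units pragma and no units argument given")
        return cls(df, units=resolved)


# ---------------------------------------------------------------- filters

def filter_samples_by_mapped_reads(
    m: ExpressionMatrix, threshold: int = DEFAULT_MIN_MAPPED_READS
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples with fewer than *threshold* total counts.

    The column sum of the count matrix proxies "reads mapped to the
    transcriptome".  Returns the filtered matrix and the excluded sample
    ids; raises if no sample survives.
    """
    if m.units != RAW_COUNTS:
        raise PreprocessError("sample read filter requires raw counts")
    totals = m.values.sum(axis=0)
    keep = totals >= threshold
    excluded = list(totals.index[~keep])
    if not keep.any():
        raise PreprocessError(
            f"all {m.n_samples} samples fall below the {threshold} mapped-read threshold"
        )
    return ExpressionMatrix(m.values.loc[:, keep], units=RAW_COUNTS), excluded


def filter_genes_by_prevalence(
    m: ExpressionMatrix, min_fraction: float = DEFAULT_MIN_PREVALENCE
) -> ExpressionMatrix:
    """Keep genes detected (count > 0) in at least ``ceil(min_fraction * n)`` samples."""
    if m.units != RAW_COUNTS:
        raise PreprocessError("gene prevalence filter requires raw counts")
    if not 0 < min_fraction <= 1:
        raise PreprocessError(f"min_fraction must be in (0, 1], got {min_fraction}")
    needed = math.ceil(min_fraction * m.n_samples)
    detected = (m.values > 0).sum(axis=1)
    keep = detected >= needed
    if not keep.any():
        raise PreprocessError("no gene passes the prevalence filter")
    return ExpressionMatrix(m.values.loc[keep], units=RAW_COUNTS)


# ----------------------------------------------------------- normalisation

def log_normalize(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount) normalisation.

    Counts-per-million removes library-size differences; the pseudocount
    keeps zeros finite (count 0 with pseudocount 1 maps to 0).  Monotone in
    the counts within each sample.
    """
    if m.units != RAW_COUNTS:
        raise PreprocessError("log_normalize requires raw counts")
    if pseudocount <= 0:
        raise PreprocessError(f"pseudocount must be > 0, got {pseudocount}")
    totals = m.values.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise PreprocessError(f"sample {bad!r} has zero total counts; filter samples first")
    cpm = m.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount), units=LOG_NORMALIZED)


def z_normalize_genes(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Center and scale each gene to mean 0, unit variance (ddof=1).

    Zero-variance genes cannot be scaled; they are dropped and returned in
    a side list so callers can audit them.
    """
    if m.n_samples < 2:
        raise PreprocessError("z-normalisation needs at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    degenerate = list(sd.index[sd == 0])
    keep = sd > 0
    if not keep.any():
        raise PreprocessError("every gene has zero variance")
    z = m.values.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(z, units=Z_SCORED), degenerate
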