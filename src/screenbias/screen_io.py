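"""I/O and sample-level QC for guide libraries, count matrices and score tables.

File dialects: both tab- and comma-delimited inputs are accepted (sniffed
from the header line); all output is tab-delimited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RPM_SCALE = 1e6

SourceTag = Literal["log2fc", "chronos", "mageck_mle"]
_VALID_SOURCE_TAGS = ("log2fc", "chronos", "mageck_mle")

SAMPLE_META_COLUMNS = ["sample", "screen_id", "replicate", "timepoint_day", "doublings", "media"]


def _sniff_sep(path: str | Path) -> str:
    """Return the delimiter of a text table: tab if the header contains one."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def rpm_normalize(counts: np.ndarray | pd.Series | Sequence[float]) -> np.ndarray | pd.Series:
    """Scale a count vector to reads per million.

    Each entry becomes ``count / sum(counts) * 1e6``; the result sums to 1e6.
    Idempotent up to floating point: an RPM vector maps to itself.

    Raises
    ------
    ValueError
        If the vector sums to zero or contains negative entries.
    """
    is_series = isinstance(counts, pd.Series)
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot RPM-normalize an all-zero count vector")
    out = arr / total * RPM_SCALE
    if is_series:
        return pd.Series(out, index=counts.index, name=counts.name)
    return out


@dataclass(frozen=True)
class GuideLibrary:
    """A guide construct library: construct -> gene map with pDNA representation.

    ``table`` is indexed by ``construct_id`` and carries columns ``gene``,
    ``is_control``, ``pdna_count`` and the derived ``pdna_rpm`` view.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "is_control", "pdna_count"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate construct_id: {dup!r}")
        if (t["pdna_count"] < 0).any():
            bad = t.index[t["pdna_count"] < 0][0]
            raise ValueError(f"negative pdna_count for construct {bad!r}")
        if "pdna_rpm" not in t.columns:
            t = t.copy()
            t["pdna_rpm"] = rpm_normalize(t["pdna_count"].to_numpy())
            object.__setattr__(self, "table", t)

    @property
    def construct_ids(self) -> pd.Index:
        return self.table.index

    @property
    def genes(self) -> pd.Index:
        """Unique gene universe, controls excluded."""
        non_ctrl = self.table.loc[~self.table["is_control"], "gene"]
        return pd.Index(pd.unique(non_ctrl), name="gene")

    @property
    def pdna_rpm(self) -> pd.Series:
        return self.table["pdna_rpm"]

    @property
    def n_constructs(self) -> int:
        return len(self.table)

    def gene_pdna_rpm(self) -> pd.Series:
        """Per-gene mean pDNA RPM over a gene's constructs (controls excluded)."""
        t = self.table.loc[~self.table["is_control"]]
        return t.groupby("gene")["pdna_rpm"].mean().rename("pdna_rpm")

    def constructs_for(self, gene: str) -> pd.Index:
        return self.table.index[self.table["gene"] == gene]


def read_library(path: str | Path) -> GuideLibrary:
    """Read a library table (TSV/CSV with construct_id, gene, is_control, pdna_count).

    Parsing is order-preserving; the RPM view is computed on read.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"construct_id": str, "gene": str})
    required = ["construct_id", "gene", "is_control", "pdna_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["is_control"] = _coerce_bool(df["is_control"])
    df["pdna_count"] = pd.to_numeric(df["pdna_count"], errors="raise")
    return GuideLibrary(df.set_index("construct_id"))


def write_library(library: GuideLibrary, path: str | Path) -> None:
    library.table.drop(columns="pdna_rpm").to_csv(path, sep="\t", index_label="construct_id")


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise ValueError(f"cannot interpret is_control value {bad!r} as boolean")
    return out


@dataclass(frozen=True)
class SampleQC:
    """Per-sample quality metrics and the exclusion decision."""

    skew_ratio: float
    dropout_fraction: float
    reads_per_construct: float
    timepoint_day: int
    excluded: bool


#: Samples with more than this fraction of undetected constructs are excluded
#: when harvested before EXCLUSION_DAY.
DROPOUT_LIMIT = 0.005
EXCLUSION_DAY = 21


def sample_qc(counts: np.ndarray | pd.Series, timepoint_day: int) -> SampleQC:
    """Compute skew ratio, dropout fraction and the exclusion decision.

    Skew ratio is the 90th/10th percentile ratio of raw construct counts
    (linear-interpolated percentiles); a zero 10th percentile yields an
    infinity sentinel. A sample is excluded iff more than 0.5% of constructs
    are undetected at a timepoint earlier than day 21.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    p10, p90 = np.percentile(arr, [10, 90])
    skew = float("inf") if p10 == 0 else float(p90 / p10)
    dropout = float((arr == 0).mean())
    excluded = dropout > DROPOUT_LIMIT and timepoint_day < EXCLUSION_DAY
    return SampleQC(
        skew_ratio=skew,
        dropout_fraction=dropout,
        reads_per_construct=float(arr.mean()),
        timepoint_day=int(timepoint_day),
        excluded=excluded,
    )


@dataclass
class CountMatrix:
    """Constructs x samples counts with per-sample metadata.

    ``values`` rows align to a :class:`GuideLibrary`; ``samples`` is indexed by
    sample name with columns screen_id, replicate, timepoint_day, doublings,
    media. ``normalization`` states whether values are raw counts or RPM;
    mixing is an error by construction.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalization: Literal["raw", "rpm"] = "raw"

    def __post_init__(self) -> None:
        if self.normalization not in ("raw", "rpm"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not self.values.columns.equals(self.samples.index):
            missing = self.values.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)}")
            self.samples = self.samples.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def construct_ids(self) -> pd.Index:
        return self.values.index

    def to_rpm(self) -> "CountMatrix":
        if self.normalization == "rpm":
            return self
        rpm = self.values.apply(lambda col: rpm_normalize(col.to_numpy()), axis=0)
        rpm.index = self.values.index
        return CountMatrix(rpm, self.samples.copy(), normalization="rpm")

    def qc(self) -> pd.DataFrame:
        """Per-sample QC table (raw counts required)."""
        if self.normalization != "raw":
            raise ValueError("sample QC is defined on raw counts")
        rows = {}
        for s in self.values.columns:
            q = sample_qc(self.values[s], int(self.samples.loc[s, "timepoint_day"]))
            rows[s] = {
                "skew_ratio": q.skew_ratio,
                "dropout_fraction": q.dropout_fraction,
                "reads_per_construct": q.reads_per_construct,
                "timepoint_day": q.timepoint_day,
                "excluded": q.excluded,
            }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")

    def drop_excluded(self) -> "CountMatrix":
        keep = self.qc().query("~excluded").index
        return CountMatrix(self.values[keep], self.samples.loc[keep], self.normalization)


def read_count_matrix(
    counts_path: str | Path,
    meta_path: str | Path,
    normalization: Literal["raw", "rpm"] = "raw",
) -> CountMatrix:
    """Read a count matrix TSV/CSV (first column construct_id) plus sidecar metadata."""
    sep = _sniff_sep(counts_path)
    values = pd.read_csv(counts_path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    values.index.name = "construct_id"
    meta = pd.read_csv(meta_path, sep=_sniff_sep(meta_path))
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path}: missing metadata columns {missing}")
    meta = meta.set_index("sample")
    return CountMatrix(values, meta, normalization=normalization)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    matrix.values.to_csv(counts_path, sep="\t", index_label="construct_id")
    matrix.samples.to_csv(meta_path, sep="\t", index_label="sample")


@dataclass
class GeneEffectMatrix:
    """Genes x screens effect scores with a provenance tag.

    Rows are unique gene symbols (no control labels); values are finite.
    """

    values: pd.DataFrame
    source_tag: SourceTag = "log2fc"

    def __post_init__(self) -> None:
        if self.source_tag not in _VALID_SOURCE_TAGS:
            raise ValueError(
                f"source_tag must be one of {_VALID_SOURCE_TAGS}, got {self.source_tag!r}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene row: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("gene effect scores must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def screens(self) -> pd.Index:
        return self.values.columns


def import_scores(
    path: str | Path,
    source_tag: SourceTag,
    library: GuideLibrary | None = None,
) -> GeneEffectMatrix:
    """Import an externally produced genes x screens score table.

    Genes absent from ``library`` (including control labels) are dropped with
    a warning. Non-numeric cells raise with their row/column location.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            bad_genes = df.index[coerced.isna() & df[col].notna()]
            if len(bad_genes):
                raise ValueError(
                    f"{path}: non-numeric value at gene {bad_genes[0]!r}, screen {col!r}"
                )
        df[col] = coerced
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"{path}: non-numeric value at gene {gene!r}, screen {col!r}")
    if library is not None:
        known = set(library.genes)
        unknown = [g for g in df.index if g not in known]
        if unknown:
            warnings.warn(
                f"dropping {len(unknown)} rows absent from the library gene universe "
                f"(e.g. {unknown[:3]})",
                stacklevel=2,
            )
            logger.warning("import_scores: dropped %d unknown gene rows", len(unknown))
            df = df.drop(index=unknown)
    return GeneEffectMatrix(df.astype(float), source_tag=source_tag)


def write_scores(matrix: GeneEffectMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line; blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
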