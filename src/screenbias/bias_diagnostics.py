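"""Equal-count-bin representation-bias diagnostics.

Genes are sorted by initial pDNA representation and split into equally sized
bins; the median of a per-gene statistic (by default the mean absolute gene
effect score across screens) is rank-correlated against the per-bin mean
pDNA. A strong negative Spearman rho indicates that poorly represented genes
carry systematically more extreme scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from screenbias.screen_io import GeneEffectMatrix

DEFAULT_N_BINS = 20
DEFAULT_LOESS_SPAN = 0.75


@dataclass(frozen=True)
class BinPartition:
    """Equal-count assignment of genes to representation bins.

    ``assignment`` maps gene -> bin index in [0, n_bins); ``key`` carries the
    ordering value (pDNA RPM) per gene. Bin sizes differ by at most one gene
    and bin index is non-decreasing in the key.
    """

    n_bins: int
    assignment: pd.Series
    key: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.assignment.index

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def mean_key_per_bin(self) -> pd.Series:
        return self.key.groupby(self.assignment).mean()


def equal_count_bins(values: pd.Series, n_bins: int = DEFAULT_N_BINS) -> BinPartition:
    """Split genes into ``n_bins`` contiguous bins of (near-)equal size.

    Genes are sorted by (value, label) ascending; when n_genes is not a
    multiple of n_bins the remainder genes go to the lowest bins.
    """
    n = len(values)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if n_bins > n:
        raise ValueError(f"n_bins ({n_bins}) exceeds number of genes ({n})")
    ordered = values.loc[sorted(values.index)].sort_values(kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    idx = np.repeat(np.arange(n_bins), sizes)
    assignment = pd.Series(idx, index=ordered.index, name="bin").reindex(values.index)
    return BinPartition(n_bins=n_bins, assignment=assignment, key=values.copy())


def mean_abs_score(scores: GeneEffectMatrix | pd.DataFrame,
                   screens: list[str] | None = None) -> pd.Series:
    """Per-gene mean of absolute scores across (a subset of) screens."""
    values = scores.values if isinstance(scores, GeneEffectMatrix) else scores
    if screens is not None:
        if not screens:
            raise ValueError("need at least one screen")
        values = values[screens]
    return values.abs().mean(axis=1).rename("mean_abs_score")


@dataclass(frozen=True)
class BinSummary:
    bin: int
    mean_pdna: float
    median: float
    q25: float
    q75: float
    sd: float
    n: int


@dataclass(frozen=True)
class BiasResult:
    """Spearman rank correlation of per-bin medians against per-bin mean pDNA."""

    rho: float
    p_value: float
    bins: list[BinSummary]
    degenerate: bool = False
    method: str = "spearman"
    smoothed: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "p_value": self.p_value,
            "n_bins": self.n_bins,
            "degenerate": self.degenerate,
            "method": self.method,
            "bins": [vars(b) for b in self.bins],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _summarize_bins(per_gene_stat: pd.Series, partition: BinPartition) -> list[BinSummary]:
    stat = per_gene_stat.reindex(partition.genes)
    if stat.isna().any():
        missing = stat.index[stat.isna()][0]
        raise ValueError(f"gene {missing!r} in partition carries no statistic")
    out = []
    groups = stat.groupby(partition.assignment)
    mean_pdna = partition.mean_key_per_bin()
    for b, vals in groups:
        arr = vals.to_numpy(dtype=float)
        q25, med, q75 = np.percentile(arr, [25, 50, 75])
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        out.append(BinSummary(bin=int(b), mean_pdna=float(mean_pdna.loc[b]),
                              median=float(med), q25=float(q25), q75=float(q75),
                              sd=sd, n=int(arr.size)))
    return sorted(out, key=lambda s: s.bin)


def representation_bias(
    per_gene_stat: pd.Series,
    partition: BinPartition,
    method: str = "spearman",
    loess_span: float | None = None,
) -> BiasResult:
    """Correlate per-bin medians of a per-gene statistic with mean pDNA per bin.

    One point per bin; Spearman with average ranks for ties (Pearson behind
    the ``method`` flag). All-identical medians yield rho 0, p 1 and the
    degenerate flag.
    """
    bins = _summarize_bins(per_gene_stat, partition)
    x = np.array([b.mean_pdna for b in bins])
    y = np.array([b.median for b in bins])
    if np.allclose(y, y[0]):
        result = BiasResult(rho=0.0, p_value=1.0, bins=bins, degenerate=True, method=method)
    else:
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        result = BiasResult(rho=float(rho), p_value=float(p), bins=bins, method=method)
    if loess_span is not None:
        smoothed = loess_bins(bins, span=loess_span)
        result = BiasResult(rho=result.rho, p_value=result.p_value, bins=bins,
                            degenerate=result.degenerate, method=method, smoothed=smoothed)
    return result


def per_bin_sd_profile(per_gene_stat: pd.Series, partition: BinPartition) -> pd.Series:
    """Sample SD (n-1 denominator) of the statistic within each bin.

    Size-one bins report NaN (SD undefined).
    """
    bins = _summarize_bins(per_gene_stat, partition)
    return pd.Series({b.bin: b.sd for b in bins}, name="sd").rename_axis("bin")


def difference_bias(
    scores_a: GeneEffectMatrix | pd.DataFrame,
    scores_b: GeneEffectMatrix | pd.DataFrame,
    partition: BinPartition,
    pairs: list[tuple[str, str]] | None = None,
    method: str = "spearman",
) -> BiasResult:
    """Bias diagnostic on the per-gene mean absolute difference of two score sets.

    ``pairs`` lists matched (screen_a, screen_b) columns; by default columns
    are paired positionally. The partition should be keyed on the appropriate
    pDNA (mean of the two libraries for cross-library mode).
    """
    va = scores_a.values if isinstance(scores_a, GeneEffectMatrix) else scores_a
    vb = scores_b.values if isinstance(scores_b, GeneEffectMatrix) else scores_b
    shared = va.index.intersection(vb.index)
    if shared.empty:
        raise ValueError("the two score matrices share no genes")
    if pairs is None:
        pairs = list(zip(va.columns, vb.columns))
    diffs = pd.DataFrame(
        {f"{a}|{b}": (va.loc[shared, a] - vb.loc[shared, b]).abs() for a, b in pairs}
    )
    per_gene = diffs.mean(axis=1).rename("mean_abs_diff")
    sub = BinPartition(
        n_bins=partition.n_bins,
        assignment=partition.assignment.loc[shared],
        key=partition.key.loc[shared],
    )
    return representation_bias(per_gene, sub, method=method)


def loess_bins(bins: list[BinSummary], span: float = DEFAULT_LOESS_SPAN) -> np.ndarray | None:
    """LOESS-smooth the per-bin medians over mean pDNA (display only).

    Returns the smoothed medians at the bin abscissae, or None with a warning
    when fewer than 4 bins are available.
    """
    if len(bins) < 4:
        warnings.warn("fewer than 4 bins; LOESS smoothing skipped", stacklevel=2)
        return None
    x = np.array([b.mean_pdna for b in bins])
    y = np.array([b.median for b in bins])
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted)
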