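"""Post-hoc bias corrections and the screen-comparability evaluation battery.

Corrections: per-bin z-scoring of gene effect scores and low-representation
filtering (with a matched random-removal control). Evaluation: grouped
pairwise correlations, PCA pairwise distances, and rank-sum testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from screenbias.bias_diagnostics import BinPartition
from screenbias.screen_io import GeneEffectMatrix

DEFAULT_THRESHOLD_RPM = 50.0


def zscore_by_bin(scores: GeneEffectMatrix, partition: BinPartition,
                  across_screens: bool = False) -> GeneEffectMatrix:
    """Standardize gene effect scores within each pDNA bin.

    Default mode standardizes each (bin, screen) group separately with sample
    SD (n-1). ``across_screens`` pools all screens of a bin into one group.
    Zero-SD groups map to all-zero z-scores with a warning; size-one bins are
    an error (SD undefined).
    """
    values = scores.values
    assignment = partition.assignment.reindex(values.index)
    if assignment.isna().any():
        raise ValueError("partition does not cover the score matrix's gene universe")
    sizes = assignment.value_counts()
    if (sizes < 2).any():
        raise ValueError("bins of size 1 have undefined SD; use a coarser partition")
    out = values.copy().astype(float)
    warned = False
    for b, idx in values.groupby(assignment).groups.items():
        block = values.loc[idx]
        if across_screens:
            mu, sd = block.to_numpy().mean(), block.to_numpy().std(ddof=1)
            if sd == 0:
                out.loc[idx] = 0.0
                warned = True
            else:
                out.loc[idx] = (block - mu) / sd
        else:
            mu = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            zero = sd == 0
            if zero.any():
                warned = True
            safe_sd = sd.replace(0.0, np.nan)
            z = (block - mu) / safe_sd
            out.loc[idx] = z.fillna(0.0)
    if warned:
        warnings.warn("zero-SD bin groups mapped to all-zero z-scores", stacklevel=2)
    return GeneEffectMatrix(out, source_tag=scores.source_tag)


def filter_low_representation(
    values: pd.DataFrame,
    pdna: pd.Series,
    threshold_rpm: float = DEFAULT_THRESHOLD_RPM,
    mode: str = "low",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Drop low-representation units, or a matched random set of high ones.

    ``low`` mode removes units with pdna < threshold; ``matched_random_high``
    removes the same number of units sampled uniformly without replacement
    from those with pdna >= threshold (the paper-style control condition).
    """
    if threshold_rpm < 0:
        raise ValueError("threshold must be non-negative")
    key = pdna.reindex(values.index)
    if key.isna().any():
        raise ValueError("pdna values missing for some units")
    low = key < threshold_rpm
    if mode == "low":
        return values.loc[~low]
    if mode == "matched_random_high":
        n_remove = int(low.sum())
        high_units = values.index[~low]
        if n_remove > len(high_units):
            raise ValueError(
                f"cannot remove {n_remove} high-representation units; only {len(high_units)} exist"
            )
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        drop = gen.choice(high_units, size=n_remove, replace=False)
        return values.drop(index=drop)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class PcaDistanceReport:
    """Screen coordinates in PC space plus all pairwise Euclidean distances."""

    coordinates: pd.DataFrame  # screens x PCs
    distances: pd.DataFrame  # symmetric, zero diagonal
    variance_explained: np.ndarray

    def pair_distances(self) -> pd.Series:
        """Upper-triangle distances as a flat series keyed by screen pair."""
        screens = self.distances.index
        pairs = list(itertools.combinations(screens, 2))
        return pd.Series(
            [self.distances.loc[a, b] for a, b in pairs],
            index=pd.Index([f"{a}|{b}" for a, b in pairs], name="pair"),
            name="distance",
        )

    def to_dict(self) -> dict:
        return {
            "variance_explained": list(map(float, self.variance_explained)),
            "coordinates": {
                s: list(map(float, row)) for s, row in self.coordinates.iterrows()
            },
            "distances": self.pair_distances().to_dict(),
        }


def pca_distances(values: pd.DataFrame, n_pc: int = 2) -> PcaDistanceReport:
    """PCA of screens in gene space and pairwise Euclidean distances.

    Genes with missing values in any screen are dropped, scores are centered
    per gene (no variance scaling — effect scores share a scale), screens are
    projected onto the top ``n_pc`` components.
    """
    n_screens = values.shape[1]
    if n_screens < 3:
        raise ValueError("need at least 3 screens for a distance comparison")
    if n_pc >= n_screens:
        raise ValueError(f"n_pc ({n_pc}) must be smaller than the number of screens ({n_screens})")
    clean = values.dropna(axis=0)
    x = clean.to_numpy(dtype=float).T  # screens x genes
    x = x - x.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_pc, svd_solver="full")
    coords = pca.fit_transform(x)
    coord_df = pd.DataFrame(coords, index=values.columns,
                            columns=[f"PC{i + 1}" for i in range(n_pc)])
    dist = squareform(pdist(coords))
    dist_df = pd.DataFrame(dist, index=values.columns, columns=values.columns)
    return PcaDistanceReport(coordinates=coord_df, distances=dist_df,
                             variance_explained=pca.explained_variance_ratio_)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    paired: bool
    degenerate: bool = False


def wilcoxon_compare(values_a, values_b, paired: bool = False) -> WilcoxonResult:
    """Two-sided Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    All-zero paired differences are degenerate: flagged, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired mode requires equal-length samples")
        diffs = a - b
        if np.all(diffs == 0):
            return WilcoxonResult(statistic=0.0, p_value=1.0, paired=True, degenerate=True)
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                              paired=True)
    res = stats.ranksums(a, b, alternative="two-sided")
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          paired=False)


@dataclass(frozen=True)
class CorrelationGroupReport:
    """Grouped pairwise screen correlations with a rank-sum comparison.

    same_cell_line: rho of (same cell line, different library) pairs;
    same_library: rho of (different cell line, same library) pairs.
    """

    same_cell_line: pd.Series
    same_library: pd.Series
    wilcoxon: WilcoxonResult | None

    def to_dict(self) -> dict:
        return {
            "same_cell_line_diff_library": self.same_cell_line.to_dict(),
            "diff_cell_line_same_library": self.same_library.to_dict(),
            "wilcoxon": None if self.wilcoxon is None else vars(self.wilcoxon),
        }


def _pair_corr(values: pd.DataFrame, a: str, b: str, method: str) -> float:
    x = values[[a, b]].dropna()
    if method == "spearman":
        rho, _ = stats.spearmanr(x[a], x[b])
    else:
        rho, _ = stats.pearsonr(x[a], x[b])
    return float(rho)


def correlation_groups(
    scores: GeneEffectMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "spearman",
) -> CorrelationGroupReport:
    """Compare (same cell line, different library) vs (different cell line, same library).

    ``metadata`` is indexed by screen with columns cell_line and library.
    Every admissible unordered screen pair lands in exactly one group;
    same-cell-line pairs are excluded from the same-library group. A two-sided
    Wilcoxon rank-sum compares the two rho distributions (skipped with a
    warning when either group has fewer than 2 pairs).
    """
    values = scores.values if isinstance(scores, GeneEffectMatrix) else scores
    meta = metadata.loc[values.columns]
    same_cl, same_lib = {}, {}
    for a, b in itertools.combinations(values.columns, 2):
        cl_equal = meta.loc[a, "cell_line"] == meta.loc[b, "cell_line"]
        lib_equal = meta.loc[a, "library"] == meta.loc[b, "library"]
        if cl_equal and not lib_equal:
            same_cl[f"{a}|{b}"] = _pair_corr(values, a, b, method)
        elif lib_equal and not cl_equal:
            same_lib[f"{a}|{b}"] = _pair_corr(values, a, b, method)
    s_cl = pd.Series(same_cl, dtype=float, name="rho")
    s_lib = pd.Series(same_lib, dtype=float, name="rho")
    wres = None
    if len(s_cl) >= 2 and len(s_lib) >= 2:
        wres = wilcoxon_compare(s_cl.to_numpy(), s_lib.to_numpy(), paired=False)
    else:
        warnings.warn("a comparison group has fewer than 2 pairs; rank-sum skipped",
                      stacklevel=2)
    return CorrelationGroupReport(same_cell_line=s_cl, same_library=s_lib, wilcoxon=wres)
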