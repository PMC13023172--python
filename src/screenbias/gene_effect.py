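"""Gene effect scoring: log2 fold change, rank-based essential calling, recall.

Scores are per-construct log2 ratios of RPM abundance at a later timepoint
versus the reference, averaged to genes. Essential genes are the bottom
fraction (default 15%) of a screen's gene scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from screenbias.screen_io import CountMatrix, GeneEffectMatrix, GuideLibrary

DEFAULT_PSEUDOCOUNT = 1.0  # RPM added to numerator and denominator
DEFAULT_FRACTION = 0.15


def log2_fold_change(
    counts_t: pd.Series,
    counts_0: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-construct score log2((t + pc) / (t0 + pc)) on RPM vectors.

    Both vectors must share the construct index; the pseudocount keeps
    dropouts finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not counts_t.index.equals(counts_0.index):
        raise ValueError("construct indices of the two timepoints do not match")
    return pd.Series(
        np.log2((counts_t.to_numpy(dtype=float) + pseudocount)
                / (counts_0.to_numpy(dtype=float) + pseudocount)),
        index=counts_t.index,
        name="log2fc",
    )


def score_screens(
    matrix: CountMatrix,
    library: GuideLibrary,
    reference: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    timepoint: str = "final",
) -> GeneEffectMatrix:
    """Compute per-gene log2FC scores for every screen in a count matrix.

    The reference defaults to the library pDNA RPM. ``timepoint`` selects
    which sample per screen to score: "final" (default, largest doublings)
    or "all" (every post-reference sample becomes a column).
    """
    rpm = matrix.to_rpm()
    if reference is None:
        reference = library.pdna_rpm.reindex(rpm.construct_ids)
    cols = {}
    for screen_id, group in rpm.samples.groupby("screen_id", sort=False):
        ordered = group.sort_values("doublings")
        post = ordered[ordered["doublings"] > 0]
        if post.empty:
            continue
        chosen = [post.index[-1]] if timepoint == "final" else list(post.index)
        for s in chosen:
            label = str(screen_id) if timepoint == "final" else f"{screen_id}:{s}"
            cols[label] = log2_fold_change(rpm.values[s], reference, pseudocount)
    construct_scores = pd.DataFrame(cols)
    return aggregate_to_genes(construct_scores, library)


def aggregate_to_genes(
    construct_scores: pd.DataFrame | pd.Series,
    library: GuideLibrary,
) -> GeneEffectMatrix:
    """Average construct scores to genes; controls are excluded.

    Genes with no surviving constructs are dropped with a warning.
    """
    if isinstance(construct_scores, pd.Series):
        construct_scores = construct_scores.to_frame("score")
    gene_map = library.table["gene"].reindex(construct_scores.index)
    is_ctrl = library.table["is_control"].reindex(construct_scores.index)
    if gene_map.isna().any():
        missing = construct_scores.index[gene_map.isna()][0]
        raise ValueError(f"construct {missing!r} not present in the library")
    keep = ~is_ctrl.astype(bool)
    scored = construct_scores.loc[keep]
    if scored.empty:
        warnings.warn("all scored constructs are controls; gene matrix is empty", stacklevel=2)
        empty = pd.DataFrame(index=pd.Index([], name="gene"), columns=construct_scores.columns,
                             dtype=float)
        return GeneEffectMatrix(empty, source_tag="log2fc")
    by_gene = scored.groupby(gene_map.loc[keep]).mean()
    dropped = library.genes.difference(by_gene.index)
    if len(dropped):
        warnings.warn(f"{len(dropped)} library genes had no scored constructs", stacklevel=2)
    by_gene.index.name = "gene"
    return GeneEffectMatrix(by_gene.astype(float), source_tag="log2fc")


@dataclass(frozen=True)
class EssentialCall:
    """A rank-based essential gene call for one screen (or averaged scores)."""

    genes: frozenset[str]
    fraction: float
    n_universe: int
    basis: str = "per_screen"
    ordered: tuple[str, ...] = field(default=(), repr=False)

    def __len__(self) -> int:
        return len(self.genes)

    def flags(self, universe: pd.Index) -> pd.Series:
        """Boolean essential flag aligned to ``universe``."""
        return pd.Series([g in self.genes for g in universe], index=universe, name="is_essential")


def call_essentials(scores: pd.Series, fraction: float = DEFAULT_FRACTION,
                    basis: str = "per_screen") -> EssentialCall:
    """Flag the bottom floor(fraction * n) genes by ascending score.

    Ties at the boundary break by ascending gene label, so calls are
    deterministic across platforms.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(scores)
    k = math.floor(fraction * n)
    if k < 1:
        raise ValueError(f"cannot select at least one gene: n={n}, fraction={fraction}")
    # stable sort on a label-presorted index gives the ascending-label tiebreak
    order = scores.loc[sorted(scores.index)].sort_values(kind="mergesort")
    chosen = tuple(order.index[:k])
    return EssentialCall(genes=frozenset(chosen), fraction=fraction, n_universe=n,
                         basis=basis, ordered=chosen)


def recall_common_essentials(call: EssentialCall, reference: list[str] | set[str],
                             universe: pd.Index | None = None) -> float:
    """Fraction of the reference essential list recovered by the call.

    Reference genes absent from the score universe are dropped from the
    denominator so the metric reflects screen quality, not library content.
    """
    ref = set(reference)
    if universe is not None:
        ref &= set(universe)
    if not ref:
        raise ValueError("reference list has no genes in common with the score universe")
    return len(call.genes & ref) / len(ref)


def fnr_fpr_curves(
    scores: pd.Series,
    reference: set[str] | list[str],
    control_flags: pd.Series | None = None,
    k_grid: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """FNR of reference essentials and FPR of control units versus bottom-k.

    ``scores`` may mix genes and control units; ``control_flags`` marks the
    controls. Returns a frame indexed by k with columns fnr (and fpr when
    controls are present).
    """
    ref = set(reference) & set(scores.index)
    if not ref:
        raise ValueError("no reference genes present among the scored units")
    order = scores.loc[sorted(scores.index)].sort_values(kind="mergesort").index
    if k_grid is None:
        k_grid = np.arange(0, len(scores) + 1)
    controls: set[str] = set()
    if control_flags is not None:
        controls = set(control_flags.index[control_flags.astype(bool)])
    if control_flags is not None and not controls:
        warnings.warn("no control units flagged; FPR curve omitted", stacklevel=2)
    is_ref = np.fromiter((u in ref for u in order), dtype=bool, count=len(order))
    cum_ref = np.concatenate([[0], np.cumsum(is_ref)])
    out = {"fnr": 1.0 - cum_ref[np.asarray(k_grid)] / len(ref)}
    if controls:
        is_ctrl = np.fromiter((u in controls for u in order), dtype=bool, count=len(order))
        cum_ctrl = np.concatenate([[0], np.cumsum(is_ctrl)])
        out["fpr"] = cum_ctrl[np.asarray(k_grid)] / len(controls)
    return pd.DataFrame(out, index=pd.Index(np.asarray(k_grid), name="k"))


def pairwise_overlap(call_a: EssentialCall, call_b: EssentialCall) -> dict[str, float]:
    """Overlap count and Jaccard index of two essential calls."""
    inter = call_a.genes & call_b.genes
    union = call_a.genes | call_b.genes
    return {
        "overlap": len(inter),
        "jaccard": len(inter) / len(union) if union else float("nan"),
    }
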