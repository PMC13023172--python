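"""Generative model of a pooled CRISPR knockout screen with ground truth.

The mechanism: construct representation is log-normal, cells receive guides
in proportion to it, fitness acts multiplicatively per population doubling
(2^(dd*(1+s)), so a gene with fitness s depletes by ~s*d log2 units after d
doublings), and every passage bottleneck and sequencing step is an integer
multinomial draw. Sampling variance therefore grows as representation falls
— the structure the bias diagnostics are designed to detect — while true
essentiality is assigned independently of representation (the null the
false-positive estimator assumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from screenbias.bias_diagnostics import BinPartition
from screenbias.gene_effect import EssentialCall
from screenbias.screen_io import CountMatrix, GuideLibrary, _sniff_sep


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the screen generator.

    Coverage defaults (500 cells and 500 reads per construct), the ~14
    population-doubling horizon with >= 3 timepoints, and the ~15% essential
    fraction with negative fitness mirror a typical pooled knockout screen
    protocol. ``pdna_sigma`` sets the log-normal dispersion of construct
    representation (default spans roughly three orders of magnitude in RPM).
    ``fitness_noise_sd`` adds a small per-screen, per-gene fitness jitter —
    the representation-independent noise floor that dominates once sampling
    noise is driven down by very high coverage.
    """

    n_genes: int = 2000
    constructs_per_gene: int = 1
    f_essential: float = 0.15
    s_min: float = -0.5
    s_max: float = -0.1
    f_enriching: float = 0.0
    s_enrich_max: float = 0.3
    pdna_mu: float = 0.0
    pdna_sigma: float = 1.15
    coverage_cells: float = 500.0
    coverage_reads: float = 500.0
    doublings: tuple[float, ...] = (0.0, 5.0, 10.0, 14.0)
    fitness_noise_sd: float = 0.01
    n_libraries: int = 1
    n_screens: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_essential < 1:
            raise ValueError("f_essential must lie in (0, 1)")
        if self.coverage_cells < 1 or self.coverage_reads < 1:
            raise ValueError("coverage values must be >= 1")
        d = self.doublings
        if len(d) < 1 or d[0] != 0 or any(b < a for a, b in zip(d, d[1:])):
            raise ValueError("doublings must be non-decreasing and start at 0")
        if self.n_genes < 2 or self.constructs_per_gene < 1:
            raise ValueError("need at least 2 genes and 1 construct per gene")

    @property
    def n_constructs(self) -> int:
        return self.n_genes * self.constructs_per_gene


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: per-gene fitness/essential flags and per-library weights."""

    genes: pd.DataFrame  # index gene; columns fitness, is_essential
    construct_weights: dict[str, pd.Series]  # library id -> per-construct weight

    @property
    def essential_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["is_essential"]])

    def fitness_for_constructs(self, library: GuideLibrary) -> pd.Series:
        return self.genes["fitness"].reindex(library.table["gene"]).set_axis(
            library.construct_ids
        )


def _gene_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_libraries(config: SimConfig) -> tuple[list[GuideLibrary], SimTruth]:
    """Draw library realizations sharing one gene-level truth.

    Each library gets independent log-normal construct weights; pDNA counts
    are a multinomial read-out of the weights at ``coverage_reads`` depth.
    Essentiality is assigned independently of representation.
    """
    root = np.random.SeedSequence(config.seed)
    truth_seq, *lib_seqs = root.spawn(1 + config.n_libraries)
    rng = np.random.default_rng(truth_seq)

    genes = _gene_labels(config.n_genes)
    n_ess = math.floor(config.f_essential * config.n_genes)
    fitness = np.zeros(config.n_genes)
    ess_idx = rng.choice(config.n_genes, size=n_ess, replace=False)
    fitness[ess_idx] = rng.uniform(config.s_min, config.s_max, size=n_ess)
    is_ess = np.zeros(config.n_genes, dtype=bool)
    is_ess[ess_idx] = True
    if config.f_enriching > 0:
        non_ess = np.flatnonzero(~is_ess)
        n_enr = math.floor(config.f_enriching * config.n_genes)
        enr_idx = rng.choice(non_ess, size=min(n_enr, len(non_ess)), replace=False)
        fitness[enr_idx] = rng.uniform(0.0, config.s_enrich_max, size=len(enr_idx))
    truth_genes = pd.DataFrame(
        {"fitness": fitness, "is_essential": is_ess},
        index=pd.Index(genes, name="gene"),
    )

    construct_ids = [
        f"{g}_c{j}" for g in genes for j in range(config.constructs_per_gene)
    ]
    gene_per_construct = np.repeat(genes, config.constructs_per_gene)
    total_reads = int(round(config.coverage_reads * config.n_constructs))

    libraries: list[GuideLibrary] = []
    weights: dict[str, pd.Series] = {}
    for i, seq in enumerate(lib_seqs):
        lrng = np.random.default_rng(seq)
        lib_id = f"lib{i}"
        w = lrng.lognormal(config.pdna_mu, config.pdna_sigma, size=config.n_constructs)
        counts = lrng.multinomial(total_reads, w / w.sum())
        table = pd.DataFrame(
            {
                "gene": gene_per_construct,
                "is_control": False,
                "pdna_count": counts.astype(float),
            },
            index=pd.Index(construct_ids, name="construct_id"),
        )
        libraries.append(GuideLibrary(table))
        weights[lib_id] = pd.Series(w, index=construct_ids, name="weight")

    return libraries, SimTruth(genes=truth_genes, construct_weights=weights)


def simulate_library(config: SimConfig) -> tuple[GuideLibrary, SimTruth]:
    """Single-library convenience wrapper around :func:`simulate_libraries`."""
    libs, truth = simulate_libraries(replace(config, n_libraries=1))
    return libs[0], truth


def simulate_screen(
    library: GuideLibrary,
    truth: SimTruth,
    config: SimConfig,
    screen_id: str = "S1",
    library_id: str = "lib0",
    seed: int | np.random.SeedSequence | None = None,
    replicate: int = 1,
    media: str = "DMEM",
) -> CountMatrix:
    """Run one screen: bottlenecked growth plus multinomial sequencing.

    The initial cell pool is a multinomial draw over the library's true
    construct weights at ``coverage_cells`` depth. Between consecutive
    timepoints dd doublings apart, each construct's expectation is multiplied
    by 2^(dd*(1+s)), then the pool is bottlenecked back to the fixed cell
    total; each scheduled timepoint is sequenced at ``coverage_reads`` depth.
    Per-stage RNG streams keep earlier timepoints invariant when the schedule
    is extended.
    """
    if isinstance(seed, np.random.SeedSequence):
        seq = seed
    else:
        # offset entropy so screen streams never collide with library streams
        seq = np.random.SeedSequence([config.seed if seed is None else seed, 65537])
    n_constructs = library.n_constructs
    total_cells = int(round(config.coverage_cells * n_constructs))
    total_reads = int(round(config.coverage_reads * n_constructs))
    weights = truth.construct_weights[library_id].reindex(library.construct_ids)
    s = truth.fitness_for_constructs(library).to_numpy()

    stage_seqs = iter(seq.spawn(2 + 2 * len(config.doublings)))
    init_rng = np.random.default_rng(next(stage_seqs))
    noise_rng = np.random.default_rng(next(stage_seqs))
    if config.fitness_noise_sd > 0:
        gene_noise = noise_rng.normal(0.0, config.fitness_noise_sd, size=len(truth.genes))
        noise = pd.Series(gene_noise, index=truth.genes.index).reindex(
            library.table["gene"]
        ).to_numpy()
        s = s + noise

    cells = init_rng.multinomial(total_cells, (weights / weights.sum()).to_numpy())
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    prev_d = 0.0
    for d in config.doublings:
        grow_rng = np.random.default_rng(next(stage_seqs))
        read_rng = np.random.default_rng(next(stage_seqs))
        dd = d - prev_d
        if dd > 0:
            expected = cells * np.exp2(dd * (1.0 + s))
            tot = expected.sum()
            if tot <= 0:
                raise RuntimeError("entire cell pool went extinct during growth")
            cells = grow_rng.multinomial(total_cells, expected / tot)
        prev_d = d
        cell_total = cells.sum()
        if cell_total <= 0:
            raise RuntimeError("entire cell pool went extinct at the bottleneck")
        reads = read_rng.multinomial(total_reads, cells / cell_total)
        sample = f"{screen_id}_d{d:g}"
        columns[sample] = reads
        meta_rows.append(
            {
                "sample": sample,
                "screen_id": screen_id,
                "replicate": replicate,
                "timepoint_day": int(round(d)),
                "doublings": float(d),
                "media": media,
            }
        )

    values = pd.DataFrame(columns, index=library.construct_ids, dtype=float)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(values, meta, normalization="raw")


def simulate_panel(
    config: SimConfig,
    library: GuideLibrary | None = None,
    truth: SimTruth | None = None,
    library_id: str = "lib0",
) -> tuple[GuideLibrary, SimTruth, CountMatrix]:
    """Simulate ``config.n_screens`` independent screens of one library.

    Returns the library, the truth, and one concatenated count matrix whose
    samples carry screen ids S1..Sn.
    """
    if library is None or truth is None:
        library, truth = simulate_library(config)
    root = np.random.SeedSequence([config.seed, 104729])
    screen_seqs = root.spawn(config.n_screens)
    mats = [
        simulate_screen(
            library, truth, config, screen_id=f"S{i + 1}", library_id=library_id,
            seed=screen_seqs[i], replicate=i + 1,
        )
        for i in range(config.n_screens)
    ]
    values = pd.concat([m.values for m in mats], axis=1)
    meta = pd.concat([m.samples for m in mats], axis=0)
    return library, truth, CountMatrix(values, meta, normalization="raw")


def truth_confusion(
    truth: SimTruth,
    call: EssentialCall,
    partition: BinPartition | None = None,
) -> dict:
    """Confusion counts of a call against simulated truth (optionally per bin)."""
    universe = truth.genes.index
    called = pd.Series([g in call.genes for g in universe], index=universe)
    essential = truth.genes["is_essential"]
    out = {
        "tp": int((called & essential).sum()),
        "fp": int((called & ~essential).sum()),
        "fn": int((~called & essential).sum()),
        "tn": int((~called & ~essential).sum()),
    }
    if partition is not None:
        fp_flags = (called & ~essential).reindex(partition.genes).astype(bool)
        fn_flags = (~called & essential).reindex(partition.genes).astype(bool)
        out["fp_per_bin"] = fp_flags.groupby(partition.assignment).sum().to_dict()
        out["fn_per_bin"] = fn_flags.groupby(partition.assignment).sum().to_dict()
    return out


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth.genes.to_csv(path, sep="\t", index_label="gene")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col="gene")
    df["is_essential"] = df["is_essential"].astype(bool)
    return df
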