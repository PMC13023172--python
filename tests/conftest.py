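import numpy as np
import pandas as pd
import pytest

from screenbias.screen_io import CountMatrix, GeneEffectMatrix, GuideLibrary


@pytest.fixture
def small_library() -> GuideLibrary:
    """Six constructs over three genes plus one control."""
    table = pd.DataFrame(
        {
            "gene": ["GA", "GA", "GB", "GB", "GC", "CTRL"],
            "is_control": [False, False, False, False, False, True],
            "pdna_count": [10.0, 30.0, 5.0, 15.0, 40.0, 20.0],
        },
        index=pd.Index(["c1", "c2", "c3", "c4", "c5", "ctrl1"], name="construct_id"),
    )
    return GuideLibrary(table)


@pytest.fixture
def library_file(tmp_path):
    def _write(rows, sep="\t", name="library.tsv"):
        path = tmp_path / name
        header = sep.join(["construct_id", "gene", "is_control", "pdna_count"])
        lines = [header] + [sep.join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def score_matrix() -> GeneEffectMatrix:
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(40)]
    values = pd.DataFrame(
        rng.normal(size=(40, 3)),
        index=pd.Index(genes, name="gene"),
        columns=["S1", "S2", "S3"],
    )
    return GeneEffectMatrix(values)


@pytest.fixture
def count_matrix(small_library) -> CountMatrix:
    values = pd.DataFrame(
        {
            "s0": [100.0, 300.0, 50.0, 150.0, 400.0, 200.0],
            "s1": [50.0, 200.0, 10.0, 100.0, 500.0, 210.0],
        },
        index=small_library.construct_ids,
    )
    samples = pd.DataFrame(
        {
            "screen_id": ["X", "X"],
            "replicate": [1, 1],
            "timepoint_day": [0, 14],
            "doublings": [0.0, 14.0],
            "media": ["DMEM", "DMEM"],
        },
        index=pd.Index(["s0", "s1"], name="sample"),
    )
    return CountMatrix(values, samples)
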