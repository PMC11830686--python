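import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seropanel import MfiMatrix, PipelineConfig

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_wide_csv(tmp_path):
    """3 samples x 2 markers, linear MFI."""
    path = tmp_path / "tiny_wide.csv"
    path.write_text(
        "sample_id,CCL4|IgG,TMPO|IgA\n"
        "s1,1024,300\n"
        "s2,2048,310\n"
        "s3,512,290\n"
    )
    return path


@pytest.fixture
def tiny_long_csv(tmp_path):
    """Same data as tiny_wide_csv in long form."""
    path = tmp_path / "tiny_long.csv"
    rows = ["sample_id,marker_id,isotype,mfi"]
    data = {"s1": (1024, 300), "s2": (2048, 310), "s3": (512, 290)}
    for sid, (a, b) in data.items():
        rows.append(f"{sid},CCL4,IgG,{a}")
        rows.append(f"{sid},TMPO,IgA,{b}")
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def tiny_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "group": ["SjD", "SjD", "HC"],
            "cohort": ["hannover", "berlin", "hannover"],
            "ro_ssa_positive": [True, False, False],
        }
    )


@pytest.fixture
def small_matrix(rng):
    """20 samples x 5 markers on the centered analysis scale."""
    vals = rng.normal(0, 0.5, size=(20, 5))
    vals -= np.median(vals, axis=1, keepdims=True)
    df = pd.DataFrame(
        vals,
        index=[f"s{i:02d}" for i in range(20)],
        columns=["A|IgG", "B|IgG", "C|IgG", "D|IgA", "E|IgA"],
    )
    return MfiMatrix(df, scale="log2_centered")


@pytest.fixture
def config():
    return PipelineConfig()
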