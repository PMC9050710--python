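import numpy as np
import pandas as pd
import pytest

from pdxcna.genome import build_bin_grid


@pytest.fixture(scope="session")
def toy_arms() -> pd.DataFrame:
    """Two 10 Mb chromosomes, contiguous p|q arms of 5 Mb each."""
    rows = []
    for c in ("1", "2"):
        rows.append({"chromosome": c, "start": 0, "end": 5_000_000, "arm": "p"})
        rows.append({"chromosome": c, "start": 5_000_000, "end": 10_000_000, "arm": "q"})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_grid(toy_arms):
    return build_bin_grid(toy_arms, bin_width=1_000_000)


def make_segments(sample_id, rows):
    """rows: (chromosome, start, end, log2_ratio) tuples."""
    return pd.DataFrame(
        [
            {"sample_id": sample_id, "chromosome": c, "start": s, "end": e,
             "log2_ratio": v}
            for c, s, e, v in rows
        ]
    )


def flat_sample(grid, value=0.0, sample_id="s"):
    """A BinnedSample covering the whole grid with one constant value."""
    from pdxcna.segments import BinnedSample

    return BinnedSample(
        sample_id=sample_id,
        values=np.full(grid.n_bins, float(value)),
        mask=np.ones(grid.n_bins, dtype=bool),
    )
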