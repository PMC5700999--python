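import numpy as np
import pandas as pd
import pytest

from coipscore.io_formats import QuantTable


def make_design(n_reps: int = 4) -> pd.DataFrame:
    rows = []
    for cond, prefix in (("control", "ctrl"), ("stress", "hs")):
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "run_id": f"{prefix}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "crosslinker": rep > n_reps // 2,
                }
            )
    return pd.DataFrame(rows)


def make_quant(values: dict[str, list[float]], n_reps: int = 4) -> QuantTable:
    """Build a QuantTable from protein -> [ctrl..., stress...] rows; None = missing."""
    design = make_design(n_reps)
    data = {
        pid: [np.nan if v is None else float(v) for v in row]
        for pid, row in values.items()
    }
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(design["run_id"]))
    frame.index.name = "protein_id"
    return QuantTable(intensities=frame, design=design)


@pytest.fixture
def design_tsv(tmp_path):
    path = tmp_path / "design.tsv"
    make_design(2).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def quant_table():
    """Two proteins, 4+4 runs: one flat, one strongly stress-enriched."""
    return make_quant(
        {
            "flat": [1e6] * 8,
            "up": [1e5, 1.2e5, 0.9e5, 1.1e5, 1e7, 1.1e7, 0.9e7, 1.05e7],
        }
    )
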