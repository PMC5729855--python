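import numpy as np
import pandas as pd
import pytest

from radscreen import CountMatrix, SampleTable, SimConfig, simulate_dataset


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            [[2.0, 4.0], [4.0, 8.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
    )


@pytest.fixture
def study_design() -> pd.DataFrame:
    """The 3 timepoint x 6 dose x 3 replicate design with one dropped control."""
    return SimConfig(n_genes=1).sample_design()


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Small noise-free dataset: 10 linear, 2 spike, 188 null genes."""
    config = SimConfig(n_genes=200, seed=11, zero_noise=True)
    return config, *simulate_dataset(config)


def make_fc_table(per_gene: dict, timepoint: int = 2) -> pd.DataFrame:
    """Build a FoldChangeTable from {gene: {dose: fc or None}} (None = absent)."""
    rows = []
    for gene, fcs in per_gene.items():
        for dose, fc in fcs.items():
            rows.append(
                {
                    "gene_id": gene,
                    "timepoint_days": timepoint,
                    "dose_roentgen": float(dose),
                    "fold_change": np.nan if fc is None else float(fc),
                    "status": "absent_below_cutoff" if fc is None else "defined",
                }
            )
    return pd.DataFrame(rows)
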