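import pandas as pd
import pytest

import clonetrace as ct


@pytest.fixture(scope="session")
def small_library():
    return ct.generate_barcode_library(40, min_pairwise_distance=3, seed=11)


@pytest.fixture(scope="session")
def tiny_experiment(tmp_path_factory, small_library):
    """A small error-free transplant: 1 group, 2 mice, modest depth."""
    cfg = ct.young_reference_config(
        seed=5, n_mice=2, n_cells_transplanted=100, transduction_fraction=0.3,
        read_depth=20_000, error_rate=0.0,
    )
    outdir = tmp_path_factory.mktemp("tiny_fastq")
    res = ct.simulate_experiment(cfg, library=small_library, outdir=outdir)
    res["config"] = cfg
    return res


def make_sample_sheet(mouse="m1", gfp=0.5, n_cells=10, transduction=1.0,
                      lineages=("B", "T", "M", "E"), group="young"):
    return pd.DataFrame(
        [
            {
                "mouse": mouse, "group": group, "lineage": lin,
                "gfp_fraction": gfp, "n_cells_transplanted": n_cells,
                "transduction_fraction": transduction,
            }
            for lin in lineages
        ]
    )
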