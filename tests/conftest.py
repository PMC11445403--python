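import numpy as np
import pandas as pd
import pytest

from vectorsweep import pipeline
from vectorsweep.panel import GenotypeMatrix, PhenotypedPanel


def make_matrix(haplotypes: np.ndarray, chrom: str = "2L",
                positions=None) -> GenotypeMatrix:
    """GenotypeMatrix from a (n_sites, 2*n_samples) haplotype array."""
    haps = np.asarray(haplotypes, dtype=np.int8)
    n_sites = haps.shape[0]
    positions = positions if positions is not None else np.arange(1, n_sites + 1)
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "ref": "A", "alt": "T"})
    return GenotypeMatrix(haps.reshape(n_sites, -1, 2), sites)


def make_panel(n_resistant: int, n_susceptible: int,
               n_control: int = 0) -> PhenotypedPanel:
    return PhenotypedPanel.from_groups(
        [f"R{i}" for i in range(n_resistant)],
        [f"S{i}" for i in range(n_susceptible)],
        [f"C{i}" for i in range(n_control)])


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Synthetic demo bundle, pipeline already run once."""
    outdir = tmp_path_factory.mktemp("demo")
    config = pipeline.make_demo(outdir, seed=7)
    report = pipeline.run_pipeline(config)
    return {"dir": outdir, "config": config, "report": report}
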