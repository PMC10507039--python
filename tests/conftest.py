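import numpy as np
import pandas as pd
import pytest

from circkit.io import Gene, GeneModel, Transcript
from circkit.simulate import SimulationConfig, simulate_counts, simulate_gene_models


@pytest.fixture(scope="session")
def six_exon_model() -> GeneModel:
    """Two genes: a plus-strand 6-exon transcript and a minus-strand
    4-exon transcript, with regular 100 bp exons and 400 bp introns."""
    model = GeneModel()
    exons_plus = [(1000 + i * 500, 1100 + i * 500) for i in range(6)]
    g1 = Gene(gene_id="GPLUS", gene_name="GPLUS", chrom="chr1", strand="+")
    g1.transcripts["GPLUS.t1"] = Transcript("GPLUS.t1", exons=exons_plus)
    model.genes["GPLUS"] = g1
    exons_minus = [(20000 + i * 500, 20100 + i * 500) for i in range(4)]
    g2 = Gene(gene_id="GMINUS", gene_name="GMINUS", chrom="chr1", strand="-")
    g2.transcripts["GMINUS.t1"] = Transcript("GMINUS.t1", exons=exons_minus)
    model.genes["GMINUS"] = g2
    return model


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    config = SimulationConfig(
        seed=42,
        n_genes=60,
        n_junctions=150,
        samples_per_cell_type={"DA": 4, "TCPY": 4, "MCPY": 4, "PBMC": 4, "FB": 4},
        condition_split=0.0,
        library_size_range=(400_000, 800_000),
    )
    models, hosts = simulate_gene_models(config)
    counts, linear, design, truth = simulate_counts(models, config, hosts)
    return {
        "config": config,
        "models": models,
        "hosts": hosts,
        "counts": counts,
        "linear": linear,
        "design": design,
        "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


def make_design(samples: dict[str, int], library_size: int = 1_000_000) -> pd.DataFrame:
    rows = []
    for ct, n in samples.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{ct}_{i}",
                    "cell_type": ct,
                    "condition": "HC",
                    "sex": "M" if i % 2 else "F",
                    "age": 70.0 + i,
                    "PMI": 10.0,
                    "RIN": 7.5,
                    "library_size": library_size,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
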