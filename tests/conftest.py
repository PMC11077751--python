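import numpy as np
import pandas as pd
import pytest

from editome.io_formats import GenomeRef, SnpSet, Transcript, TranscriptModel
from editome.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    cfg = SimulationConfig(n_genes=40, n_true_sites=300, n_paired_sites=60,
                           n_unpaired_events=30, n_dte_genes=8, seed=7)
    return simulate_all(cfg)


@pytest.fixture()
def toy_genome():
    # one 400-base chromosome, deterministic
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    return GenomeRef({"chrT": seq})


@pytest.fixture()
def toy_model():
    """Two genes: plus-strand coding (2 exons) and minus-strand coding."""
    # plus gene: exons 11-100 and 201-300; CDS 41-100 + 201-240 (100 codons*3=... 60+40=100 -> not /3)
    tx_plus = Transcript("gp.t1", "gp", "chrT", "+",
                         exons=[(11, 100), (201, 300)],
                         cds=[(41, 100), (201, 230)])  # 60 + 30 = 90 nt
    tx_minus = Transcript("gm.t1", "gm", "chrT", "-",
                          exons=[(311, 340), (361, 390)],
                          cds=[(321, 340), (361, 370)])  # 20 + 10 = 30 nt
    genes = pd.DataFrame(
        [
            {"gene_id": "gp", "chrom": "chrT", "start": 11, "end": 300,
             "strand": "+"},
            {"gene_id": "gm", "chrom": "chrT", "start": 311, "end": 390,
             "strand": "-"},
        ]
    )
    return TranscriptModel(genes, {"gp.t1": tx_plus, "gm.t1": tx_minus})


@pytest.fixture()
def empty_snps():
    return SnpSet(set())


def make_reads(rows):
    """rows: (read_id, chrom, start, strand, bases, sample)."""
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "strand", "bases", "sample"],
    )


@pytest.fixture()
def two_rep_sheet():
    return pd.DataFrame(
        [
            {"sample": "T1_r1", "timepoint": "T1", "replicate": 1},
            {"sample": "T1_r2", "timepoint": "T1", "replicate": 2},
            {"sample": "T2_r1", "timepoint": "T2", "replicate": 1},
            {"sample": "T2_r2", "timepoint": "T2", "replicate": 2},
        ]
    )
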