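import numpy as np
import pandas as pd
import pytest

from exonflow import SimulationConfig, compute_exon_stats, simulate_dataset
from exonflow.simulate import write_simulation


@pytest.fixture(scope="session")
def sim_small():
    """A small paired case study with planted splicing and DE events."""
    config = SimulationConfig(
        n_genes=40,
        n_pairs=10,
        as_fraction=0.2,
        gene_de_fraction=0.2,
        background_fraction=0.1,
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def exon_stats_small(sim_small):
    dataset, _ = sim_small
    return compute_exon_stats(dataset)


@pytest.fixture()
def sim_files(tmp_path, sim_small):
    """The small case study written out as its flat files."""
    dataset, truth = sim_small
    return write_simulation(dataset, truth, tmp_path / "sim")


@pytest.fixture()
def tiny_files(tmp_path):
    """A hand-written 4-probeset / 4-sample case study on disk."""
    expr = tmp_path / "expression.tsv"
    expr.write_text(
        "probeset_id\tS1\tS2\tS3\tS4\n"
        "PS1\t8.0\t8.1\t7.9\t8.2\n"
        "PS2\t6.5\t6.4\t6.6\t6.5\n"
        "PS3\t9.1\t9.0\t9.2\t9.3\n"
        "PS4\t5.0\t5.1\t4.9\t5.2\n"
    )
    meta = tmp_path / "metadata.csv"
    meta.write_text(
        "sample_id,condition,patient_id,gender,age\n"
        "S1,normal,P1,M,61\n"
        "S2,pathological,P1,M,61\n"
        "S3,normal,P2,F,55\n"
        "S4,pathological,P2,F,55\n"
    )
    ann = tmp_path / "annotation.tsv"
    ann.write_text(
        "probeset_id\ttranscript_cluster_id\tgene_id\tchrom\tstart\tstop\tstrand"
        "\texon_index\tisoform_ids\tgene_symbol\tgene_aliases\n"
        "PS1\tTC1\tGA\tchr1\t100\t200\t+\t1\tNM_1;NM_2\tALPHA\tALF;A1\n"
        "PS2\tTC1\tGA\tchr1\t300\t400\t+\t2\tNM_1\tALPHA\tALF;A1\n"
        "PS3\tTC2\tGB\tchr2\t100\t200\t-\t1\tNM_3\tBETA\t\n"
        "PS4\tTC2\tGB\tchr2\t300\t400\t-\t2\t\tBETA\t\n"
    )
    dabg = tmp_path / "dabg.tsv"
    dabg.write_text(
        "probeset_id\tS1\tS2\tS3\tS4\n"
        "PS1\t0.001\t0.002\t0.001\t0.003\n"
        "PS2\t0.01\t0.02\t0.01\t0.02\n"
        "PS3\t0.001\t0.001\t0.001\t0.001\n"
        "PS4\t0.9\t0.8\t0.95\t0.7\n"
    )
    sets = tmp_path / "gene_sets.tsv"
    sets.write_text(
        "set_id\tgene_id\tkind\n"
        "PW1\tGA\tpathway\n"
        "PW1\tGB\tpathway\n"
        "GO:1\tGA\tgo\n"
    )
    return {
        "expression": expr,
        "metadata": meta,
        "annotation": ann,
        "dabg": dabg,
        "gene_sets": sets,
        "dir": tmp_path,
    }


@pytest.fixture()
def two_group_labels():
    def make(n_a: int, n_b: int) -> pd.Series:
        labels = ["normal"] * n_a + ["pathological"] * n_b
        return pd.Series(labels, index=[f"S{i}" for i in range(n_a + n_b)])

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
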