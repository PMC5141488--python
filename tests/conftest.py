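import pytest

import neuromine as nm


@pytest.fixture(scope="session")
def catalog():
    return nm.load_motif_catalog()


@pytest.fixture(scope="session")
def canonical_benchmark(tmp_path_factory):
    """The canonical synthetic benchmark (30 true precursors + 70 decoys,
    seed 17) mined once per session."""
    outdir = tmp_path_factory.mktemp("bench")
    config = nm.GeneratorConfig(seed=17, n_true=30, n_decoys=70)
    fasta_path, truth_path = nm.generate_benchmark_set(config, outdir)
    entries = nm.mine_catalog(
        fasta_path, config=nm.PipelineConfig(input_alphabet="protein")
    )
    return entries, truth_path
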