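import pytest

from pansynteny.pipeline import PipelineConfig, run
from pansynteny.simulate import SimConfig, simulate_pangenome


def small_config(seed: int = 11) -> SimConfig:
    """A fast 8-genome pangenome with four planted families."""
    return SimConfig(
        n_genomes=8,
        genes_per_genome=180,
        n_orphan_families=4,
        family_conservation=[1.0, 1.0, 0.5, 1.0],
        neighbor_preservation=[1.0, 1.0, 1.0, 0.25],
        shared_spread=(1.0, 0.5),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """(directory, config, truth) for the small synthetic pangenome."""
    d = tmp_path_factory.mktemp("smallsim")
    cfg = small_config()
    truth = simulate_pangenome(cfg, d)
    return d, cfg, truth


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline run under the default study conditions (25 genomes,
    ~400 genes, 20 planted families)."""
    sim = tmp_path_factory.mktemp("studysim")
    out = tmp_path_factory.mktemp("studyout")
    sim_cfg = SimConfig(seed=7)
    truth = simulate_pangenome(sim_cfg, sim)
    pipe_cfg = PipelineConfig(
        proteome_dir=str(sim),
        annotation_tsv=str(sim / "annotations.tsv"),
        ko_pathway_tsv=str(sim / "ko_pathway.tsv"),
        out_dir=str(out),
        seed=7,
    )
    run(pipe_cfg)
    return sim, out, sim_cfg, pipe_cfg, truth
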