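import logging

import pytest

from capregulon import simulate as sim
from capregulon.pipeline import PipelineConfig, run_all

logging.getLogger("capregulon").setLevel(logging.WARNING)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A complete synthetic study (genome, tracks, counts, peaks, truth)
    generated once per session with the default bundled promoter scenarios."""
    out = tmp_path_factory.mktemp("sim")
    result = sim.simulate_all(sim.SimulationConfig(seed=FIXTURE_SEED), out, seed=FIXTURE_SEED)
    result["dir"] = out
    return result


@pytest.fixture(scope="session")
def pipeline_result(sim_dir, tmp_path_factory):
    """Full pipeline run over the session synthetic study."""
    simdir = sim_dir["dir"]
    out = tmp_path_factory.mktemp("pipe")
    config = PipelineConfig(
        gff=str(simdir / "annotation.gff3"),
        fasta=str(simdir / "genome.fa"),
        bedgraphs=[
            (str(simdir / f"rep{i}.plus.bedgraph"), str(simdir / f"rep{i}.minus.bedgraph"))
            for i in (1, 2)
        ],
        counts=str(simdir / "counts.tsv"),
        metadata=str(simdir / "metadata.tsv"),
        peaks=str(simdir / "peaks.bed"),
        consensus=sim.DEFAULT_CONSENSUS,
        outdir=str(out),
        seed=FIXTURE_SEED,
        log_level="WARNING",
    )
    result = run_all(config)
    result["config"] = config
    result["truth"] = sim_dir["truth"]
    result["tracks"] = sim_dir["tracks"]
    return result
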