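import numpy as np
import pytest

from l1evo import pipeline, simulate as sim


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default simulation, shared by tests that
    score mining, classification and dating against the truth tables."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.PipelineConfig(outdir=str(out), seed=0)
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast simulation (4 families, 12 copies each)."""
    cfg = sim.SimConfig(
        seed=7, genome_length=1_500_000, n_families=4,
        family_activity_times=(6.4, 4.6, 2.2, 0.25), copies_per_family=12,
        promoter_replacement_events=((1, "F"), (2, "A")))
    genome, truth = sim.simulate(cfg)
    element, promoters = sim.build_ancestral_element(cfg.seed,
                                                     cfg.promoter_library)
    refs = sim.reference_set(element)
    refs["promoters"] = promoters
    return cfg, genome, truth, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
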