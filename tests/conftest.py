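import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example_substrates():
    from haircut.substrate_model import example_substrate_set

    return example_substrate_set()


@pytest.fixture(scope="session")
def mixing_run(tmp_path_factory):
    """One full mixing experiment (500 + 500 cells) simulated and processed.

    Session-scoped: the end-to-end recovery, downsampling and conservation
    checks all read from this single run.
    """
    from haircut.pipeline import _iter_pairs, process_read_pairs
    from haircut.simulate import make_mixing_config, simulate_experiment

    outdir = tmp_path_factory.mktemp("mixing_sim")
    cfg = make_mixing_config(500, depth=40.0, doublet_rate=0.05, seed=11)
    truth = simulate_experiment(cfg, outdir)
    result = process_read_pairs(
        _iter_pairs(outdir / "r1.fastq.gz", outdir / "r2.fastq.gz"),
        truth.whitelist,
        cfg.substrates,
        cells=truth.cell_barcodes(),
    )
    return {"cfg": cfg, "truth": truth, "result": result, "outdir": outdir}
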