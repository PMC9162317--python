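import pytest

from heightmr.simulate import PopulationSpec, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A two-population cohort small enough for fast end-to-end tests."""
    cfg = SimConfig(
        n_individuals=2500, n_variants=80, n_phecodes=12,
        baseline_prevalence_range=(0.15, 0.35),
        populations=(PopulationSpec("EA", 0.7, 1.0),
                     PopulationSpec("AA", 0.3, 0.52)),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fixture_dir(small_cohort, tmp_path_factory):
    """The small cohort written out in the pipeline's external formats."""
    from heightmr.simulate import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(small_cohort, outdir)
    return outdir
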