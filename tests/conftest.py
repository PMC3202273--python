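import pytest

from famexmatrix import FixtureSpec, RunConfig, generate_fixture, run_pipeline
from famexmatrix.expression import CoDirectionSpec

#: Desk-scale bundle shared by integration tests: small enough to run in
#: seconds, large enough to exercise every loss category and planted class.
SMALL_SPEC = FixtureSpec(
    seed=7,
    n_genes=300,
    n_families=60,
    n_uncovered_genes=5,
    n_unresolvable=3,
)


def pipeline_config(bundle, out_dir, **overrides) -> RunConfig:
    """RunConfig wired to a generated fixture bundle."""
    spec = bundle.spec
    o1, o2 = spec.organisms
    kwargs = dict(
        organisms=spec.organisms,
        expr_paths=(
            bundle.paths[f"expression_{o1}"],
            bundle.paths[f"expression_{o2}"],
        ),
        annotation_paths={
            org: {
                "probe_to_transcript": bundle.paths[f"probe_to_transcript_{org}"],
                "transcript_to_protein": bundle.paths[
                    f"transcript_to_protein_{org}"
                ],
                "transcript_to_gene": bundle.paths[f"transcript_to_gene_{org}"],
            }
            for org in spec.organisms
        },
        family_file=bundle.paths["families"],
        approach="synthetic",
        similarity_file=bundle.paths["similarity"],
        form=spec.form,
        input_level=spec.expression_level,
        codirection=CoDirectionSpec("co_both"),
        out_dir=out_dir,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    return generate_fixture(SMALL_SPEC, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    cfg = pipeline_config(small_bundle, tmp_path_factory.mktemp("small_out"))
    return run_pipeline(cfg)
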