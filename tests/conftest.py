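import pytest

from mitotier import annotation_io, pipeline, simulate
from mitotier.reference import human_mt_locus_map, synthetic_rcrs_like_reference


@pytest.fixture(scope="session")
def full_reference():
    """Synthetic full-length (16,569 bp) reference with the standard locus map."""
    return synthetic_rcrs_like_reference(), human_mt_locus_map()


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory):
    """Default synthetic study: cohort, truth table, evidence tables and the
    fully annotated output of the pipeline."""
    outdir = tmp_path_factory.mktemp("sim")
    spec = simulate.default_scenario(seed=1)
    cohort, truth, reference, locus_map = simulate.generate_cohort(spec, outdir)
    simulate.generate_evidence_tables(spec, outdir)
    trna_evidence = annotation_io.read_trna_evidence(outdir / "trna_evidence.tsv")
    panels = annotation_io.read_predictor_table(outdir / "predictors.tsv")
    annotated = pipeline.annotate_cohort(
        reference, locus_map, cohort, trna_evidence, panels
    )
    return {
        "spec": spec,
        "cohort": cohort,
        "truth": truth,
        "reference": reference,
        "locus_map": locus_map,
        "annotated": annotated,
        "outdir": outdir,
    }
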