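import pytest

from spliceortho import (
    CodingStructure,
    GeneratorConfig,
    Source,
    classify_cohort,
    generate_cohort,
)
from spliceortho.coding_projection import compute_phases


def make_structure(
    lengths,
    accession="ACC",
    gene="G",
    source=Source.CURATED,
    total_exon_count=None,
):
    """Build a CodingStructure directly from coding lengths (phases derived)."""
    lengths = tuple(int(x) for x in lengths)
    return CodingStructure(
        accession=accession,
        gene_id=gene,
        source=source,
        coding_lengths=lengths,
        phases=compute_phases(lengths),
        n_internal_fully_coding=max(0, len(lengths) - 2),
        total_exon_count=total_exon_count or len(lengths),
    )


@pytest.fixture(scope="session")
def cohort42():
    """The 500-gene-pair reference cohort: uniform truth mixture, seed 42."""
    config = GeneratorConfig(n_genes=500, seed=42)
    index_a, index_b, pairs, truths = generate_cohort(config)
    return config, index_a, index_b, pairs, truths


@pytest.fixture(scope="session")
def cohort42_results(cohort42):
    """Full pipeline runs on the reference cohort, with and without predictions."""
    _, index_a, index_b, pairs, _ = cohort42
    curated_only = classify_cohort(index_a, index_b, pairs, include_predicted=False)
    with_predicted = classify_cohort(index_a, index_b, pairs, include_predicted=True)
    return {"curated": curated_only, "predicted": with_predicted}


@pytest.fixture()
def small_cohort():
    config = GeneratorConfig(n_genes=40, seed=7)
    return (config, *generate_cohort(config))
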