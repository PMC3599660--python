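import pytest

from duomir import annotate, preprocess, simulate


@pytest.fixture(scope="session")
def small_catalog():
    """Catalog of 40 hairpins plus contaminant references."""
    return simulate.generate_catalog(40, n_contaminants_per_class=3, seed=5)


@pytest.fixture(scope="session")
def zero_noise_run(small_catalog):
    """A fully processed zero-noise library pair with its truth tables.

    Reads carry no substitution errors, no length jitter and no
    low-quality reads, so the annotation stage must agree with the
    generator's bookkeeping exactly.
    """
    catalog, contaminants = small_catalog
    spec_a, spec_b = simulate.paired_specs(
        catalog,
        n_reads=15_000,
        n_de=5,
        n_specific=4,
        error_rate=0.0,
        seed=5,
        len_jitter={0: 1.0},
        min_expected_count=40,
        max_share=0.05,
    )
    reads_a, reads_b, truth_a, truth_b, truth = simulate.simulate_pair(
        catalog, contaminants, spec_a, spec_b
    )
    out = {"catalog": catalog, "contaminants": contaminants, "truth": truth,
           "specs": (spec_a, spec_b), "truths": {"A": truth_a, "B": truth_b}}
    out["clean"], out["stats"], out["tags"], out["annotations"] = {}, {}, {}, {}
    for lib, reads in (("A", reads_a), ("B", reads_b)):
        clean, stats = preprocess.clean_reads(reads, adapter=spec_a.adapter)
        out["clean"][lib] = clean
        out["stats"][lib] = stats
        out["tags"][lib] = preprocess.collapse(clean)
        out["annotations"][lib] = annotate.classify_tags(
            out["tags"][lib], contaminants, catalog
        )
    out["counts"] = annotate.aggregate_mirna_counts(out["annotations"])
    return out
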