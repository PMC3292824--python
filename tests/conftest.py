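import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from barcodegap.io import (
    AlignedRecord,
    LocusAlignment,
    SampleSheet,
    build_dataset,
)
from barcodegap.simulate import LocusModel, SimulationConfig, simulate_genus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sheet(rows):
    """rows: iterable of (accession, species, locus[, tag]) tuples."""
    recs = []
    for row in rows:
        acc, sp, locus = row[:3]
        tag = row[3] if len(row) > 3 else "self"
        recs.append(
            {
                "accession_id": acc,
                "species_label": sp,
                "locus_name": locus,
                "source_tag": tag,
            }
        )
    return SampleSheet(pd.DataFrame(recs))


@pytest.fixture
def toy_dataset():
    """Two loci, three species; spA has two identical and one variant accession."""
    locusA = LocusAlignment(
        "locusA",
        (
            AlignedRecord("a1", "ACGTACGTAC"),
            AlignedRecord("a2", "ACGTACGTAC"),
            AlignedRecord("a3", "ACGTACGTAT"),
            AlignedRecord("b1", "ACGTACGAAC"),
            AlignedRecord("b2", "ACGTACGAAC"),
            AlignedRecord("c1", "TTTTACGTAC"),
        ),
    )
    locusB = LocusAlignment(
        "locusB",
        (
            AlignedRecord("a1", "GGGGCCCC"),
            AlignedRecord("a2", "GGGGCCCC"),
            AlignedRecord("b1", "GGGGCCCC"),  # shares locusB haplotype with spA
            AlignedRecord("c1", "GGAACCCC"),
        ),
    )
    sheet = make_sheet(
        [
            ("a1", "spA", "locusA"),
            ("a2", "spA", "locusA"),
            ("a3", "spA", "locusA"),
            ("b1", "spB", "locusA"),
            ("b2", "spB", "locusA"),
            ("c1", "spC", "locusA"),
            ("a1", "spA", "locusB"),
            ("a2", "spA", "locusB"),
            ("b1", "spB", "locusB"),
            ("c1", "spC", "locusB"),
        ]
    )
    return build_dataset([locusA, locusB], sheet)


def small_genus_config(seed=7, **overrides):
    """Six-species, fast-to-analyze simulated genus for integration tests."""
    base = dict(
        n_species=6,
        accessions_per_species=3,
        loci=[
            LocusModel("nuc", 400, "nuclear"),
            LocusModel("cp1", 300, "plastid"),
            LocusModel("cp2", 300, "plastid"),
        ],
        kappa=2.0,
        inter_divergence={"nuc": 0.15, "cp1": 0.02, "cp2": 0.02},
        intra_divergence={"nuc": 0.004, "cp1": 0.0, "cp2": 0.0},
        plastid_capture_pairs=[("species_1", "species_2")],
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_genus():
    return simulate_genus(small_genus_config())
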