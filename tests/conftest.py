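import numpy as np
import pytest

from spliceshift.formats_io import EventAnnotation
from spliceshift.synthetic_cohort import CohortConfig, generate_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-type cohort with planted shifts, shared across tests."""
    config = CohortConfig(
        event_types=("SE", "AFE"),
        n_events_per_type=120,
        n_cell_types=1,
        n_treatments=2,
        seed=42,
    )
    return generate_counts(config)


@pytest.fixture
def plus_afe():
    """Plus-strand AFE whose isoform 1 is the upstream (smaller-coordinate) TSS."""
    return EventAnnotation(
        "afe_plus", "geneA", "AFE", "chr1", "+",
        isoform1_exons=((1000, 1200), (9000, 9200)),
        isoform2_exons=((3000, 3200), (9000, 9200)),
    )


@pytest.fixture
def minus_afe_iso1_downstream():
    """Minus-strand AFE where isoform 1 is the smaller-coordinate first exon.

    On the minus strand the smaller-coordinate TSS is *downstream* in
    transcription order, so oriented ΔΨ must flip sign relative to the raw
    isoform-1 convention.
    """
    return EventAnnotation(
        "afe_minus", "geneB", "AFE", "chr1", "-",
        isoform1_exons=((200, 400), (5000, 5200)),
        isoform2_exons=((200, 400), (8000, 8200)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
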