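import numpy as np
import pytest
from hypothesis import settings

import germdiv as g

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

# Printed per-primer amplicon counts of the 11-primer, 12-accession study
# this package's defaults emulate: (primer, TNA, MA, PA, printed %P,
# printed EMR, printed MI where PIC*EMR is exact).
PRIMER_COUNTS = [
    ("IRAP4352", 9, 1, 8, 89, 7.11),
    ("IRAP 4334", 11, 0, 11, 100, 11.0),
    ("IRAP 4348", 13, 3, 10, 77, 7.69),
    ("IRAP 4370", 14, 0, 14, 100, 14.0),
    ("IRAP 4377", 9, 2, 7, 78, 5.44),
    ("IRAP 4351", 3, 2, 1, 33, 0.33),
    ("IRAP 4340", 21, 0, 21, 100, 21.0),
    ("IRAP 4342", 4, 0, 4, 100, 4.0),
    ("IRAP 4375", 4, 2, 2, 50, 1.0),
    ("IRAP 3471", 5, 0, 5, 100, 5.0),
    ("IRAP 4357", 4, 2, 2, 50, 1.0),
]


@pytest.fixture(scope="session")
def alfalfa_traits():
    return g.load_alfalfa_traits()


@pytest.fixture
def small_band_matrix():
    """4 accessions x 5 bands over two primers; frequencies 1, .5, .25, .75, 0."""
    values = np.array(
        [
            [1, 1, 0, 1, 0],
            [1, 1, 1, 1, 0],
            [1, 0, 0, 1, 0],
            [1, 0, 0, 0, 0],
        ]
    )
    return g.BandMatrix(
        accession_ids=["a1", "a2", "a3", "a4"],
        band_ids=["b1", "b2", "b3", "b4", "b5"],
        primer_of_band={"b1": "P1", "b2": "P1", "b3": "P1", "b4": "P2", "b5": "P2"},
        values=values,
    )


def random_distance_matrix(rng, n):
    labels = [f"L{i}" for i in range(n)]
    M = rng.uniform(0.1, 2.0, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return g.SymmetricMatrix(labels, M, "distance")
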