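import numpy as np
import pandas as pd
import pytest

from allokaryo import CombinedReference, SpeciesGenome, WindowedCoverage
from allokaryo.presets import default_pedigree, default_reference


@pytest.fixture(scope="session")
def study_reference():
    """Six parent species + decoy, 16 chromosomes each, 10 kb windows."""
    return default_reference()


@pytest.fixture(scope="session")
def study_pedigree():
    """Eleven-node crossing scheme stacking six species."""
    return default_pedigree()


@pytest.fixture
def tiny_reference():
    """Two species x two chromosomes, no mt, 10 kb windows."""
    return CombinedReference(
        species=[
            SpeciesGenome("A", [("chr1", 1_000_000), ("chr2", 2_000_000)]),
            SpeciesGenome("B", [("chr1", 1_500_000), ("chr2", 500_000)]),
        ],
        window_size=10_000,
    )


def flat_coverage(reference, depth_by_slot):
    """Constant-depth coverage over a reference, one value per slot."""
    frames = []
    for tag, chrom in reference.nuclear_slots():
        bounds = reference.window_bounds(tag, chrom)
        frames.append(
            pd.DataFrame(
                {
                    "species": tag,
                    "chromosome": chrom,
                    "start": bounds[:, 0],
                    "end": bounds[:, 1],
                    "depth": float(depth_by_slot.get((tag, chrom), 0.0)),
                }
            )
        )
    return WindowedCoverage(pd.concat(frames, ignore_index=True))


@pytest.fixture
def make_flat_coverage():
    return flat_coverage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
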