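"""Shared fixtures: ideal lattices and seeded random frames."""

import numpy as np
import pytest

from cgbeta import DetectionParams, Frame, Grain, SheetSpec, make_parallel_sheet


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def lattice_12x32():
    """Ideal parallel sheet with closed-form ground truth (320 triples)."""
    return make_parallel_sheet(SheetSpec(n_strands=12, strand_len=32))


def random_frame(seed: int, n_min: int = 100, n_max: int = 200,
                 pep_min: int = 5, pep_max: int = 20,
                 box_edge: float = 2.5) -> Frame:
    """Dense random scatter grouped into contiguous peptides.

    The box edge is small enough that epsilon-neighbors (and hence aligned
    triples) occur at useful rates for oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    n_pep = int(rng.integers(pep_min, pep_max + 1))
    # contiguous peptide blocks covering all n grains
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_pep - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [n]])
    pts = rng.uniform(0.0, box_edge, size=(n, 3))
    grains = []
    for p in range(n_pep):
        for i in range(bounds[p], bounds[p + 1]):
            grains.append(Grain(
                grain_id=i, peptide_id=p, residue_index=i - bounds[p],
                residue_name="ALA", atom_name="BB",
                position=tuple(float(v) for v in pts[i])))
    return Frame(grains=grains, box=(box_edge,) * 3)


@pytest.fixture
def random_frame_factory():
    return random_frame
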