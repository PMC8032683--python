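"""Aligned-triple criterion, accelerated finder vs literal enumeration."""

import itertools

import numpy as np
import pytest

from cgbeta import (DetectionParams, Frame, Grain, SheetSpec, is_aligned,
                    make_helix, make_parallel_sheet, neighbor_candidates)
from cgbeta.triples import (AlignedTriple, find_aligned_triples,
                            find_aligned_triples_bruteforce)
from conftest import random_frame


def grain(gid, pep, pos):
    return Grain(gid, pep, 0, "ALA", "BB", pos)


def python_loop_oracle(frame, params):
    """Tiny-n oracle: a literal pure-Python loop over ordered triples."""
    out = set()
    for x, y, z in itertools.permutations(frame.grains, 3):
        if is_aligned(x, y, z, params):
            ea, eb = sorted((x.grain_id, z.grain_id))
            out.add(AlignedTriple(ea, y.grain_id, eb))
    return out


class TestIsAligned:
    """The three construction cases: aligned, angle-violating,
    distance-violating."""

    def setup_method(self):
        self.params = DetectionParams(alpha=0.89, epsilon=0.7)

    def test_collinear_triple_is_aligned(self):
        x = grain(0, 0, (0, 0, 0))
        y = grain(1, 1, (0.48, 0, 0))
        z = grain(2, 2, (0.96, 0, 0))
        assert is_aligned(x, y, z, self.params)
        assert is_aligned(z, y, x, self.params)  # symmetric in the ends

    def test_distance_violation_rejected(self):
        # second gap is 0.72 nm > epsilon
        x = grain(0, 0, (0, 0, 0))
        y = grain(1, 1, (0.48, 0, 0))
        z = grain(2, 2, (1.2, 0, 0))
        assert not is_aligned(x, y, z, self.params)

    def test_angle_violation_rejected(self):
        # constructed angle at y is 150 deg = 5pi/6 < 0.89*pi (160.2 deg)
        x = grain(0, 0, (0.0, 0.0, 0.0))
        y = grain(1, 1, (0.5, 0.0, 0.0))
        z = grain(2, 2, (0.933, 0.25, 0.0))
        assert not is_aligned(x, y, z, self.params)

    def test_same_peptide_rejected_even_if_collinear(self):
        x = grain(0, 0, (0, 0, 0))
        y = grain(1, 0, (0.48, 0, 0))
        z = grain(2, 1, (0.96, 0, 0))
        assert not is_aligned(x, y, z, self.params)

    def test_coincident_points_not_aligned(self):
        x = grain(0, 0, (0.48, 0, 0))
        y = grain(1, 1, (0.48, 0, 0))
        z = grain(2, 2, (0.96, 0, 0))
        assert not is_aligned(x, y, z, self.params)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_invalid_alpha_rejected(self, bad):
        with pytest.raises(ValueError):
            DetectionParams(alpha=bad)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(epsilon=0.0)


class TestNeighborCandidates:
    def test_within_epsilon_mutual(self):
        f = Frame(grains=[grain(0, 0, (0, 0, 0)), grain(1, 1, (0.69, 0, 0))])
        nbrs = neighbor_candidates(f, 0.7)
        assert nbrs[0] == {1} and nbrs[1] == {0}

    def test_beyond_epsilon_excluded(self):
        f = Frame(grains=[grain(0, 0, (0, 0, 0)), grain(1, 1, (0.71, 0, 0))])
        nbrs = neighbor_candidates(f, 0.7)
        assert nbrs[0] == set() and nbrs[1] == set()

    def test_same_peptide_excluded(self):
        f = Frame(grains=[grain(0, 0, (0, 0, 0)), grain(1, 0, (0.1, 0, 0))])
        assert neighbor_candidates(f, 0.7)[0] == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        grains = [grain(i, i % 7, tuple(rng.uniform(0, 5, 3)))
                  for i in range(100)]
        f = Frame(grains=grains)
        nbrs = neighbor_candidates(f, 0.7)
        for a in grains:
            expect = {
                b.grain_id for b in grains
                if b.grain_id != a.grain_id and b.peptide_id != a.peptide_id
                and np.linalg.norm(np.array(a.position) - b.position) <= 0.7
            }
            assert nbrs[a.grain_id] == expect


class TestFindAlignedTriples:
    def test_three_collinear_grains_one_triple(self):
        f = Frame(grains=[grain(0, 0, (0, 0, 0)), grain(1, 1, (0.48, 0, 0)),
                          grain(2, 2, (0.96, 0, 0))])
        assert find_aligned_triples(f) == {AlignedTriple(0, 1, 2)}

    def test_single_peptide_yields_nothing(self):
        assert find_aligned_triples(make_helix(30)) == set()

    def test_lattice_closed_form(self, lattice_12x32, default_params):
        triples = find_aligned_triples(lattice_12x32, default_params)
        assert len(triples) == 32 * (12 - 2)
        # every triple is a cross-strand column segment: ids differ by 32
        for t in triples:
            assert t.center - t.end_a == 32 and t.end_b - t.center == 32

    def test_duplicate_orientation_canonicalized(self):
        f = Frame(grains=[grain(5, 0, (0, 0, 0)), grain(1, 1, (0.4, 0, 0)),
                          grain(3, 2, (0.8, 0, 0))])
        triples = find_aligned_triples(f)
        assert triples == {AlignedTriple(3, 1, 5)}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_python_loop_oracle_small(self, seed):
        f = random_frame(seed, n_min=18, n_max=25, pep_min=3, pep_max=6,
                         box_edge=1.2)
        params = DetectionParams()
        assert find_aligned_triples(f, params) == python_loop_oracle(f, params)

    @pytest.mark.parametrize("seed", range(8))
    def test_dense_oracle_equals_python_loop(self, seed):
        f = random_frame(seed + 100, n_min=15, n_max=22, pep_min=3, pep_max=6,
                         box_edge=1.2)
        params = DetectionParams()
        assert (find_aligned_triples_bruteforce(f, params)
                == python_loop_oracle(f, params))

    @pytest.mark.parametrize("seed", range(10))
    def test_accelerated_equals_dense_enumeration(self, seed):
        f = random_frame(seed, n_min=100, n_max=160, pep_min=5, pep_max=20)
        params = DetectionParams()
        assert (find_aligned_triples(f, params)
                == find_aligned_triples_bruteforce(f, params))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_epsilon(self, seed):
        f = make_parallel_sheet(SheetSpec(n_strands=6, strand_len=8,
                                          jitter=0.05, seed=seed))
        t_small = find_aligned_triples(f, DetectionParams(epsilon=0.55))
        t_big = find_aligned_triples(f, DetectionParams(epsilon=0.75))
        assert t_small <= t_big

    @pytest.mark.parametrize("seed", range(5))
    def test_antimonotone_in_alpha(self, seed):
        f = make_parallel_sheet(SheetSpec(n_strands=6, strand_len=8,
                                          jitter=0.05, seed=seed))
        t_strict = find_aligned_triples(f, DetectionParams(alpha=0.95))
        t_loose = find_aligned_triples(f, DetectionParams(alpha=0.80))
        assert t_strict <= t_loose

    def test_rigid_motion_leaves_triples_unchanged(self, lattice_12x32,
                                                   default_params):
        before = find_aligned_triples(lattice_12x32, default_params)
        rng = np.random.default_rng(42)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        t = rng.normal(scale=3.0, size=3)
        moved = Frame(grains=[
            Grain(g.grain_id, g.peptide_id, g.residue_index, g.residue_name,
                  g.atom_name, tuple(q @ np.array(g.position) + t))
            for g in lattice_12x32.grains])
        assert find_aligned_triples(moved, default_params) == before

    def test_every_emitted_triple_recheck_passes(self, default_params):
        f = random_frame(7)
        by_id = {g.grain_id: g for g in f.grains}
        for t in find_aligned_triples(f, default_params):
            assert is_aligned(by_id[t.end_a], by_id[t.center],
                              by_id[t.end_b], default_params)

    def test_pbc_wraps_across_box(self):
        # collinear only through the periodic boundary
        f = Frame(grains=[grain(0, 0, (9.8, 1, 1)), grain(1, 1, (0.28, 1, 1)),
                          grain(2, 2, (0.76, 1, 1))],
                  box=(10.0, 10.0, 10.0))
        assert find_aligned_triples(f, DetectionParams(use_pbc=False)) == set()
        assert find_aligned_triples(f, DetectionParams(use_pbc=True)) == {
            AlignedTriple(0, 1, 2)}
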