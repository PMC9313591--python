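"""EFA algebra, Procrustes alignment, symmetry decomposition, taxon means."""

import numpy as np
import pandas as pd
import pytest

from petalspectrum.efa import (
    EFACoefficients,
    calibrate_harmonic_count,
    efa_forward,
    efa_inverse,
    gpa_align,
    harmonic_power,
    mean_shape_per_taxon,
    mirror_coefficients,
    remove_asymmetric_component,
)
from petalspectrum.exceptions import DegeneracyError, InputError, MappingError
from petalspectrum.outlines import Outline, SpecimenTable, resample_uniform
from petalspectrum.simulate import FlowerParams, gen_front_outline

from conftest import circle_points


class TestForward:
    def test_circle_closed_form(self, circle_outline):
        c = efa_forward(circle_outline, 8)
        a1, b1, c1, d1 = c.harmonics[0]
        assert abs(a1 - 2.0) < 1e-3 and abs(d1 - 2.0) < 1e-3
        assert abs(b1) < 1e-3 and abs(c1) < 1e-3
        assert harmonic_power(c)[0] > 0.9999

    def test_translation_moves_only_offset(self, circle_outline):
        c0 = efa_forward(circle_outline, 8)
        shifted = circle_outline.with_points(circle_outline.points + [5.0, -7.0])
        c1 = efa_forward(shifted, 8)
        assert np.abs(c1.harmonics - c0.harmonics).max() < 1e-12
        assert abs(c1.offset[0] - c0.offset[0] - 5.0) < 1e-9
        assert abs(c1.offset[1] - c0.offset[1] + 7.0) < 1e-9

    def test_aliasing_and_bad_harmonic_count(self, circle_outline):
        with pytest.raises(InputError):
            efa_forward(circle_outline, 0)
        with pytest.raises(InputError):
            efa_forward(circle_outline, 300)  # > n_points / 2

    def test_start_point_invariance_after_canonicalisation(self, front_flower):
        from petalspectrum.outlines import canonicalize_orientation

        o = resample_uniform(front_flower, 256)
        # new[j] = old[j + 37], so old landmark i sits at (i - 37) mod n
        rolled = o.with_points(
            np.roll(o.points, -37, axis=0),
            landmarks=[(i - 37) % 256 for i in o.landmarks],
        )
        c0 = efa_forward(canonicalize_orientation(o), 16)
        c1 = efa_forward(canonicalize_orientation(rolled), 16)
        assert np.abs(c0.harmonics - c1.harmonics).max() < 1e-9

    def test_rotation_equivariance(self, front_flower):
        phi = 0.7
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        c0 = efa_forward(front_flower, 12)
        c1 = efa_forward(front_flower.with_points(front_flower.points @ R.T), 12)
        h0, h1 = c0.harmonics, c1.harmonics
        # rotating the outline rotates the (a, c) and (b, d) coefficient pairs
        for col_pair in ((0, 2), (1, 3)):
            v0 = h0[:, col_pair]
            v1 = h1[:, col_pair]
            assert np.abs(v1 - v0 @ R.T).max() < 1e-9


class TestInverse:
    def test_round_trip_converges(self, front_flower):
        o = resample_uniform(front_flower, 300)
        c = efa_forward(o, 64)
        rec = efa_inverse(c, o.n_points)
        err = np.mean(np.linalg.norm(rec.points - o.points, axis=1))
        assert err < 1e-4 * o.centroid_size()

    def test_round_trip_error_decreases_in_harmonics(self, front_flower):
        o = resample_uniform(front_flower, 300)
        errs = []
        for N in (2, 4, 8, 16, 32):
            rec = efa_inverse(efa_forward(o, N), o.n_points)
            errs.append(np.mean(np.linalg.norm(rec.points - o.points, axis=1)))
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_first_harmonic_is_an_ellipse(self):
        c = EFACoefficients(np.array([[2.0, 0.0, 0.0, 1.0]]), T=2 * np.pi)
        p = efa_inverse(c, 512).points
        d1 = (np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)) / 2
        d2 = np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)
        cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        assert np.all(cross > 0)  # constant curvature sign
        kap = cross / np.linalg.norm(d1, axis=1) ** 3
        n_ext = int(np.sum((kap > np.roll(kap, 1)) & (kap > np.roll(kap, -1)))) + int(
            np.sum((kap < np.roll(kap, 1)) & (kap < np.roll(kap, -1)))
        )
        assert n_ext == 4

    def test_offset_only_gives_repeated_point(self):
        c = EFACoefficients(np.zeros((3, 4)), offset=(1.5, -2.5), T=1.0)
        p = efa_inverse(c, 64).points
        assert np.allclose(p, [1.5, -2.5])


class TestHarmonicPower:
    def test_single_harmonic(self):
        c = EFACoefficients(np.array([[1.0, 0, 0, 1.0], [0, 0, 0, 0.0]]))
        f = harmonic_power(c)
        assert f[0] == 1.0 and f[-1] == 1.0

    def test_explicit_fractions(self):
        # powers (8, 2): (a^2+b^2+c^2+d^2)/2 = 8 needs sum of squares 16
        c = EFACoefficients(np.array([[4.0, 0, 0, 0.0], [2.0, 0, 0, 0.0]]))
        assert np.allclose(harmonic_power(c), [0.8, 1.0])

    def test_non_decreasing_and_normalised(self, front_flower):
        f = harmonic_power(efa_forward(front_flower, 32))
        assert np.all(np.diff(f) >= -1e-15)
        assert abs(f[-1] - 1.0) < 1e-12

    def test_zero_power_rejected(self):
        with pytest.raises(DegeneracyError):
            harmonic_power(EFACoefficients(np.zeros((2, 4))))


class TestCalibration:
    def test_circles_need_one_harmonic(self):
        outs = [
            Outline(f"c{i}", "c", "front", circle_points(1.0 + i, 128))
            for i in range(3)
        ]
        assert calibrate_harmonic_count(outs, 0.99, 16).n_harmonics == 1

    def test_lobed_flowers_need_the_lobe_harmonic(self):
        outs = [
            resample_uniform(
                gen_front_outline(FlowerParams(petal_count=5, lobe_depth=0.3, seed=s)),
                300,
            )
            for s in range(3)
        ]
        cal = calibrate_harmonic_count(outs, 0.99, 64)
        assert cal.n_harmonics >= 5

    def test_cap_with_warning_flag(self):
        outs = [
            resample_uniform(
                gen_front_outline(FlowerParams(petal_count=5, lobe_depth=0.3, seed=s)),
                300,
            )
            for s in range(3)
        ]
        cal = calibrate_harmonic_count(outs, 0.999999, N_max=4)
        assert cal.n_harmonics == 4
        assert not cal.reached

    def test_empty_input(self):
        with pytest.raises(InputError):
            calibrate_harmonic_count([], 0.99, 8)


class TestMirrorAndSymmetry:
    def test_symmetric_shape_is_fixed_point(self):
        c = EFACoefficients(np.array([[2.0, 0, 0, 1.0], [0.5, 0, 0, 0.2]]))
        m = mirror_coefficients(c)
        assert np.array_equal(m.harmonics, c.harmonics)

    def test_involution(self, front_flower):
        c = efa_forward(front_flower, 16)
        mm = mirror_coefficients(mirror_coefficients(c))
        assert np.array_equal(mm.harmonics, c.harmonics)
        assert mm.offset == c.offset

    def test_commutes_with_geometric_mirroring(self, front_flower):
        # bilateral axis on +x: mirror geometrically across the x axis,
        # reverse to restore CCW, and compare coefficient-space mirroring
        rot = front_flower.points @ np.array([[0.0, -1.0], [1.0, 0.0]])  # axis -> +x
        o = Outline("o", "o", "front", rot)
        mir_pts = (rot * [1.0, -1.0])[::-1]
        shift = int(np.argmin(np.linalg.norm(mir_pts - rot[0], axis=1)))
        mir = Outline("m", "m", "front", np.roll(mir_pts, -shift, axis=0))
        lhs = efa_forward(mir, 16).harmonics
        rhs = mirror_coefficients(efa_forward(o, 16)).harmonics
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_removal_definition_and_idempotence(self):
        c = EFACoefficients(np.array([[2.0, 0.3, -0.1, 1.0]]), offset=(0.5, 0.2))
        r = remove_asymmetric_component(c)
        assert np.array_equal(r.harmonics, [[2.0, 0.0, 0.0, 1.0]])
        assert r.offset == (0.5, 0.0)
        r2 = remove_asymmetric_component(r)
        assert np.array_equal(r2.harmonics, r.harmonics)

    def test_output_exactly_mirror_invariant(self, front_flower):
        c = efa_forward(front_flower, 16)
        r = remove_asymmetric_component(c)
        m = mirror_coefficients(r)
        assert np.array_equal(m.harmonics, r.harmonics)
        assert m.offset == r.offset

    def test_power_conservation(self, front_flower):
        c = efa_forward(front_flower, 16)
        r = remove_asymmetric_component(c)
        sym_power = 0.5 * np.sum(c.harmonics[:, [0, 3]] ** 2)
        assert r.total_power() == sym_power

    def test_symmetric_mode_keeps_the_residual(self):
        c = EFACoefficients(np.array([[2.0, 0.3, -0.1, 1.0]]), offset=(0.5, 0.2))
        r = remove_asymmetric_component(c, component="symmetric")
        assert np.array_equal(r.harmonics, [[0.0, 0.3, -0.1, 0.0]])
        assert r.offset == (0.0, 0.2)


class TestGPA:
    def _triangle_outlines(self):
        tri = np.array([[0.0, 0], [1, 0], [0.3, 0.8], [0.5, -0.2]])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        a = Outline("a", "a", "front", tri, landmarks=[0, 1, 2, 3])
        b = Outline("b", "b", "front", tri @ R.T * 3 + [5, 6], landmarks=[0, 1, 2, 3])
        return a, b

    def test_exact_superimposability(self):
        a, b = self._triangle_outlines()
        aligned, res = gpa_align([a, b])
        rmsd = np.sqrt(
            np.mean((aligned[0].landmark_coords() - aligned[1].landmark_coords()) ** 2)
        )
        assert rmsd < 1e-9
        assert res.converged

    def test_duplicates_get_identical_transforms(self):
        a, _ = self._triangle_outlines()
        dup = Outline("a2", "a", "front", a.points.copy(), landmarks=list(a.landmarks))
        _, res = gpa_align([a, dup, a.with_points(a.points * 2.0)])
        assert abs(res.scales[0] - res.scales[1]) < 1e-12
        assert abs(res.angles[0] - res.angles[1]) < 1e-12

    def test_consensus_contract_on_random_set(self):
        rng = np.random.default_rng(8)
        outs = []
        for i in range(10):
            o = gen_front_outline(
                FlowerParams(petal_count=5, lobe_depth=0.2 + 0.05 * rng.random(),
                             dorsoventral_gradient=0.3 * rng.random(),
                             asymmetry_sd=0.02, seed=int(rng.integers(1 << 30)))
            )
            ang = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            outs.append(o.with_points(o.points @ R.T * rng.uniform(0.5, 3)))
        aligned, res = gpa_align(outs, tol=1e-10)
        assert abs(np.sqrt(np.sum(res.consensus**2)) - 1.0) < 1e-9
        assert res.converged
        # bilateral axis (top -> bottom) along +x
        axis = res.consensus[3] - res.consensus[2]
        assert abs(axis[1]) < 1e-8

    def test_errors(self):
        a, _ = self._triangle_outlines()
        with pytest.raises(InputError):
            gpa_align([a])
        line = np.column_stack([np.linspace(0, 1, 4), np.zeros(4)])
        degenerate = Outline("d", "d", "front", np.vstack([line, [[0.5, 0.0]]])[:4],
                             landmarks=[0, 1, 2, 3])
        with pytest.raises(DegeneracyError):
            gpa_align([degenerate, degenerate.with_points(degenerate.points + 1)])


class TestTaxonMeans:
    def _table(self, pairs):
        return SpecimenTable(
            pd.DataFrame(
                [{"specimen_id": s, "taxon_id": t, "clade": "c", "view": "front"}
                 for s, t in pairs]
            )
        )

    def _coeffs(self, sid, a1):
        return EFACoefficients(np.array([[a1, 0, 0, 1.0]]), specimen_id=sid,
                               taxon_id="", view="front")

    def test_identical_specimens_pass_through(self):
        tbl = self._table([("s1", "tA"), ("s2", "tA")])
        means = mean_shape_per_taxon([self._coeffs("s1", 2.0), self._coeffs("s2", 2.0)], tbl)
        assert len(means) == 1
        assert means[0].harmonics[0, 0] == 2.0

    def test_arithmetic_mean(self):
        tbl = self._table([("s1", "tA"), ("s2", "tA")])
        means = mean_shape_per_taxon([self._coeffs("s1", 1.0), self._coeffs("s2", 3.0)], tbl)
        assert means[0].harmonics[0, 0] == 2.0

    def test_taxon_counts_preserved(self):
        # 168 specimens spread over 95 taxa -> exactly 95 mean shapes
        rng = np.random.default_rng(0)
        pairs, k = [], 0
        taxa = [f"t{j}" for j in range(95)]
        counts = np.ones(95, dtype=int)
        for _ in range(168 - 95):
            counts[rng.integers(95)] += 1
        for t, c in zip(taxa, counts):
            for _ in range(c):
                pairs.append((f"s{k}", t))
                k += 1
        assert len(pairs) == 168
        tbl = self._table(pairs)
        coeffs = [self._coeffs(s, 1.0) for s, _ in pairs]
        assert len(mean_shape_per_taxon(coeffs, tbl)) == 95

    def test_unknown_specimen_rejected(self):
        tbl = self._table([("s1", "tA")])
        with pytest.raises(MappingError):
            mean_shape_per_taxon([self._coeffs("sX", 1.0)], tbl)

    def test_inconsistent_harmonic_counts_rejected(self):
        tbl = self._table([("s1", "tA"), ("s2", "tA")])
        c2 = EFACoefficients(np.array([[1.0, 0, 0, 1], [0, 0, 0, 0.1]]),
                             specimen_id="s2")
        with pytest.raises(InputError):
            mean_shape_per_taxon([self._coeffs("s1", 1.0), c2], tbl)
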