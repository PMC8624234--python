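"""Fluctuations, stiffness, collectivity, axis components and mode selection."""

import numpy as np
import pytest

from pullnma import (
    DomainMap,
    ENMParameters,
    ModeSelectionCriteria,
    axis_components,
    collectivity,
    compute_enm_modes,
    domain_mean_axis_displacement,
    effective_force_constant,
    make_helix,
    residue_stiffness,
    select_separating_modes,
    square_fluctuations,
)
from pullnma.errors import InsufficientModesError
from pullnma.structure_io import CoarseModel, ResidueId


def _chain(coords):
    coords = np.asarray(coords, dtype=float)
    return CoarseModel(
        coords=coords,
        residue_names=["ALA"] * len(coords),
        residue_ids=[ResidueId("A", i + 1) for i in range(len(coords))],
    )


class TestSquareFluctuations:
    def test_symmetric_dimer_equal(self, dimer_modes):
        f = square_fluctuations(dimer_modes, m_modes=1)
        assert f[0] == pytest.approx(f[1])

    def test_equals_hessian_pseudoinverse_trace(self, helix10, helix10_modes):
        """Full-spectrum fluctuations equal the diagonal 3x3-block traces of the
        Hessian pseudo-inverse (independent oracle)."""
        from pullnma import build_hessian

        H = build_hessian(helix10, ENMParameters(n_modes="all"))
        Hinv = np.linalg.pinv(H, rcond=1e-10, hermitian=True)
        oracle = np.array([np.trace(Hinv[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]) for i in range(10)])
        ours = square_fluctuations(helix10_modes, m_modes=helix10_modes.n_modes)
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_monotone_in_mode_count(self, helix10_modes):
        prev = np.zeros(10)
        for m in range(1, helix10_modes.n_modes + 1):
            f = square_fluctuations(helix10_modes, m_modes=m)
            assert np.all(f >= prev - 1e-12)
            prev = f

    def test_helix_ends_more_flexible_than_core(self, helix10_modes):
        f = square_fluctuations(helix10_modes, m_modes=helix10_modes.n_modes)
        assert f[0] > f[5]
        assert f[-1] > f[5]

    def test_too_many_modes_warns_and_uses_all(self, helix10_modes):
        with pytest.warns(UserWarning, match="only"):
            f = square_fluctuations(helix10_modes, m_modes=10_000)
        assert np.all(f > 0)


class TestEffectiveForceConstant:
    def test_dimer_single_spring(self, dimer_modes):
        """One spring of constant gamma: the pair stiffness is gamma itself."""
        assert effective_force_constant(dimer_modes, 0, 1) == pytest.approx(1.0)

    def test_series_springs_are_softer(self):
        """Linear trimer: the 1-3 stiffness (two springs in series) must be
        lower than the 1-2 stiffness (one spring)."""
        trimer = _chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        modes = compute_enm_modes(trimer, ENMParameters(cutoff_rc=5.0, n_modes="all"))
        k12 = effective_force_constant(modes, 0, 1)
        k13 = effective_force_constant(modes, 0, 2)
        assert k13 < k12
        # analytic: series of two unit springs -> 1/2
        assert k13 == pytest.approx(0.5)

    def test_symmetry_and_rotation_invariance(self, helix10, helix10_modes):
        from scipy.spatial.transform import Rotation

        k_ab = effective_force_constant(helix10_modes, 2, 7)
        k_ba = effective_force_constant(helix10_modes, 7, 2)
        assert k_ab == pytest.approx(k_ba)
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        rotated = helix10.with_coords(helix10.coords @ R.T + 5.0)
        modes_rot = compute_enm_modes(rotated, ENMParameters(n_modes="all"))
        assert effective_force_constant(modes_rot, 2, 7) == pytest.approx(k_ab, rel=1e-8)

    def test_partial_spectrum_refused(self, helix10):
        partial = compute_enm_modes(helix10, ENMParameters(n_modes=5))
        with pytest.raises(InsufficientModesError):
            effective_force_constant(partial, 0, 1)
        with pytest.raises(InsufficientModesError):
            residue_stiffness(partial)

    def test_stiffness_mean_matches_direct_enumeration(self, helix10_modes):
        stiff = residue_stiffness(helix10_modes)
        i = 4
        direct = np.mean(
            [effective_force_constant(helix10_modes, i, j) for j in range(10) if j != i]
        )
        assert stiff[i] == pytest.approx(direct)

    def test_dumbbell_lobe_cores_stiffer_than_linker(self, dumbbell_aligned):
        model, dm, _, modes = dumbbell_aligned
        stiff = residue_stiffness(modes)
        linker = np.setdiff1d(
            np.arange(model.n_sites), np.concatenate([dm["lobeA"], dm["lobeB"]])
        )
        assert stiff[dm["lobeA"]].mean() > stiff[linker].mean()
        assert stiff[dm["lobeB"]].mean() > stiff[linker].mean()


class TestCollectivity:
    def test_bounds_on_constructed_modes(self, helix10_modes):
        """Uniform participation gives 1; a single moving site gives 1/N."""
        import dataclasses

        uniform = np.ones(30) / np.sqrt(30)
        single = np.zeros(30)
        single[3] = 1.0
        fake = dataclasses.replace(
            helix10_modes,
            eigenvalues=np.array([1.0, 2.0]),
            eigenvectors=np.vstack([uniform, single]),
        )
        assert collectivity(fake, 1) == pytest.approx(1.0)
        assert collectivity(fake, 2) == pytest.approx(1.0 / 10)

    def test_matches_entropy_formula_on_random_vectors(self, rng):
        import dataclasses

        n = 50
        model_modes = compute_enm_modes(make_helix(n), ENMParameters(n_modes="all"))
        for _ in range(5):
            v = rng.standard_normal(3 * n)
            v /= np.linalg.norm(v)
            fake = dataclasses.replace(
                model_modes, eigenvalues=np.array([1.0]), eigenvectors=v[None, :]
            )
            p = np.sum(v.reshape(n, 3) ** 2, axis=1)
            p /= p.sum()
            oracle = float(np.exp(-np.sum(p * np.log(p)))) / n
            assert collectivity(fake, 1) == pytest.approx(oracle)
            assert 1.0 / n <= collectivity(fake, 1) <= 1.0 + 1e-12

    def test_invariant_to_sign_flip(self, helix10_modes):
        import dataclasses

        flipped = dataclasses.replace(
            helix10_modes, eigenvectors=-helix10_modes.eigenvectors
        )
        for k in (1, 2, 5):
            assert collectivity(flipped, k) == pytest.approx(collectivity(helix10_modes, k))

    def test_real_modes_within_bounds(self, dumbbell_aligned):
        modes = dumbbell_aligned[3]
        n = modes.n_sites
        for k in range(1, min(20, modes.n_modes) + 1):
            assert 1.0 / n - 1e-12 <= collectivity(modes, k) <= 1.0 + 1e-12


class TestAxisComponents:
    def test_orthogonal_axis_gives_zero(self, dimer_modes):
        # the dimer mode is purely along x
        comps = axis_components(dimer_modes, 1, (0, 0, 1.0))
        np.testing.assert_allclose(comps, 0.0, atol=1e-12)

    def test_components_sum_to_zero(self, helix10_modes):
        """Non-zero modes are orthogonal to uniform translation along the axis."""
        for k in (1, 4, 9):
            comps = axis_components(helix10_modes, k, (0, 0, 1.0))
            assert abs(comps.sum()) < 1e-10

    def test_domain_means_match_direct_loop(self, dumbbell_aligned):
        _, dm, _, modes = dumbbell_aligned
        axis = np.array([0, 0, 1.0])
        means = domain_mean_axis_displacement(modes, 6, dm, axis)
        vec = modes.mode_matrix(6)
        for name, idx in dm.items():
            loop = np.mean([vec[i] @ axis for i in idx])
            assert means[name] == pytest.approx(loop)

    def test_whole_model_domain_mean_is_zero(self, helix10_modes):
        dm = DomainMap({"all": np.arange(10)})
        means = domain_mean_axis_displacement(helix10_modes, 2, dm, (0, 0, 1.0))
        assert abs(means["all"]) < 1e-10


class TestModeSelection:
    def test_dumbbell_separating_mode_ranked_first(self, dumbbell_aligned):
        _, dm, _, modes = dumbbell_aligned
        selected, report = select_separating_modes(modes, dm)
        assert selected, "no separating mode found on the dumbbell"
        top = selected[0]
        means = domain_mean_axis_displacement(modes, top, dm)
        ma, mb = means["lobeA"], means["lobeB"]
        assert ma * mb < 0
        # symmetric dumbbell: equal magnitude, opposite sign
        assert abs(ma) == pytest.approx(abs(mb), rel=0.05)
        # its separation is the candidate maximum
        assert report.loc[report["mode"] == top, "separation"].iloc[0] == pytest.approx(
            report["separation"].max()
        )

    def test_invariant_to_domain_swap_and_axis_flip(self, dumbbell_aligned):
        _, dm, _, modes = dumbbell_aligned
        base, _ = select_separating_modes(modes, dm, (0, 0, 1.0))
        swapped_dm = DomainMap({"lobeB": dm["lobeB"], "lobeA": dm["lobeA"]})
        swapped, _ = select_separating_modes(modes, swapped_dm, (0, 0, 1.0))
        flipped, _ = select_separating_modes(modes, dm, (0, 0, -1.0))
        assert base == swapped == flipped

    def test_report_emitted_even_when_nothing_selected(self, dimer_modes):
        dm = DomainMap({"a": [0], "b": [1]})
        crit = ModeSelectionCriteria(first_k=1, of_first=1, top_collectivity=1)
        # the dimer's only mode is along x; along z nothing separates
        selected, report = select_separating_modes(dimer_modes, dm, (0, 0, 1.0), crit)
        assert selected == []
        assert len(report) == 1
        assert not report["selected"].any()

    def test_requires_two_domains(self, helix10_modes):
        with pytest.raises(ValueError):
            select_separating_modes(helix10_modes, DomainMap({"one": [0, 1]}))


class TestDomainMap:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            DomainMap({"a": [0, 1], "b": [1, 2]})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            DomainMap({"a": []})

    def test_from_ranges(self):
        model = make_helix(20)
        dm = DomainMap.from_ranges(model, {"head": "A:1-5", "tail": "A:16-20"})
        np.testing.assert_array_equal(dm["head"], np.arange(5))
        np.testing.assert_array_equal(dm["tail"], np.arange(15, 20))
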