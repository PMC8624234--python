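"""Residue-sphere exposure, buried classification and ensemble burial statistics."""

import numpy as np
import pytest

from pullnma import (
    BurialParameters,
    classify_buried,
    ensemble_burial,
    exposed_fractions,
    load_volume_table,
    make_dumbbell,
    residue_radii,
)
from pullnma.burial import burial_report, golden_spiral_points, residue_volumes
from pullnma.errors import DegenerateGeometryError, FallbackVolumeWarning
from pullnma.fixtures import DumbbellSpec
from pullnma.mode_analysis import DomainMap
from pullnma.structure_io import CoarseModel, ResidueId


def _model(coords, names=None):
    coords = np.asarray(coords, dtype=float)
    return CoarseModel(
        coords=coords,
        residue_names=list(names) if names else ["ALA"] * len(coords),
        residue_ids=[ResidueId("A", i + 1) for i in range(len(coords))],
    )


class TestRadii:
    def test_radius_volume_round_trip(self):
        model = _model([[0, 0, 0], [10, 0, 0]], names=["TRP", "GLY"])
        radii = residue_radii(model)
        table = load_volume_table()
        for r, name in zip(radii, ["TRP", "GLY"]):
            assert 4 / 3 * np.pi * r**3 == pytest.approx(table[name], abs=1e-9)

    def test_same_type_same_radius(self):
        model = _model([[0, 0, 0], [10, 0, 0]], names=["LEU", "LEU"])
        radii = residue_radii(model)
        assert radii[0] == radii[1]

    def test_radius_ordering_follows_volume_ordering(self):
        table = load_volume_table()
        names = sorted(table, key=table.get)
        coords = np.column_stack([np.arange(len(names)) * 100.0,
                                  np.zeros(len(names)), np.zeros(len(names))])
        radii = residue_radii(_model(coords, names=names))
        # ties in volume (ILE/LEU) give tied radii
        assert np.all(np.diff(radii) >= 0)
        vols = np.array([table[n] for n in names])
        assert np.all(np.diff(radii)[np.diff(vols) > 0] > 0)

    def test_unknown_residue_falls_back_with_warning(self):
        model = _model([[0, 0, 0], [10, 0, 0]], names=["XYZ", "ALA"])
        with pytest.warns(FallbackVolumeWarning):
            vols = residue_volumes(model)
        assert vols[0] == pytest.approx(load_volume_table()["GLY"])


class TestExposedFractions:
    def test_isolated_and_distant_beads_fully_exposed(self):
        model = _model([[0, 0, 0], [100.0, 0, 0]])
        fr = exposed_fractions(model.coords, residue_radii(model))
        np.testing.assert_array_equal(fr, [1.0, 1.0])

    def test_occlusion_cage(self):
        """A bead at the center of a tight icosahedral cage of larger neighbors
        is fully occluded; verified against an explicit point-rejection count."""
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([
            [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
            [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
            [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
        ], dtype=float)
        verts *= 4.0 / np.linalg.norm(verts[0])  # cage radius 4 Å
        coords = np.vstack([[0.0, 0, 0], verts])
        radii = np.array([2.0] + [4.0] * 12)
        params = BurialParameters(probe_radius=1.4, n_sphere_points=960)
        fr = exposed_fractions(coords, radii, params)
        assert fr[0] == 0.0
        # independent point-rejection oracle for the central bead
        pts = coords[0] + (radii[0] + 1.4) * golden_spiral_points(960)
        inside_any = np.zeros(len(pts), dtype=bool)
        for c, r in zip(coords[1:], radii[1:]):
            inside_any |= np.linalg.norm(pts - c, axis=1) < r + 1.4
        assert inside_any.all()

    def test_adding_neighbor_never_increases_exposure(self):
        base = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
        radii3 = np.full(3, 2.8)
        fr3 = exposed_fractions(base, radii3)
        grown = np.vstack([base, [[0, 0, 5.0]]])
        fr4 = exposed_fractions(grown, np.full(4, 2.8))
        assert np.all(fr4[:3] <= fr3 + 1e-12)

    def test_rigid_transform_invariance(self, dumbbell):
        from scipy.spatial.transform import Rotation

        model, _, _ = dumbbell
        radii = residue_radii(model)
        fr = exposed_fractions(model.coords, radii)
        R = Rotation.from_euler("xyz", [15, 75, -40], degrees=True).as_matrix()
        moved = model.coords @ R.T + np.array([3.0, -8.0, 12.0])
        fr_moved = exposed_fractions(moved, radii)
        # quadrature grid is not rotated with the molecule: agreement holds to
        # sampling tolerance
        assert np.max(np.abs(fr - fr_moved)) < 0.02
        report_a = classify_buried(fr, model)
        report_b = classify_buried(fr_moved, model)
        assert report_a.total_buried_volume == pytest.approx(
            report_b.total_buried_volume, rel=0.05, abs=100.0
        )

    def test_quadrature_convergence_on_doubling(self, dumbbell):
        model, _, _ = dumbbell
        radii = residue_radii(model)
        fr1 = exposed_fractions(model.coords, radii, BurialParameters(n_sphere_points=960))
        fr2 = exposed_fractions(model.coords, radii, BurialParameters(n_sphere_points=1920))
        assert np.max(np.abs(fr1 - fr2)) < 0.01

    def test_matches_independent_shrake_rupley(self, dumbbell):
        """Cross-check against biotite's Shrake-Rupley SASA run on the same
        sphere model (CA pseudo-atoms with our per-residue radii)."""
        import biotite.structure as struc

        from pullnma.structure_io import _to_atom_array

        model, _, _ = dumbbell
        params = BurialParameters(n_sphere_points=1920)
        radii = residue_radii(model, params)
        ours = exposed_fractions(model.coords, radii, params)

        atoms = _to_atom_array(model, model.coords)
        sasa = struc.sasa(
            atoms,
            probe_radius=params.probe_radius,
            vdw_radii=radii.astype(np.float32),
            point_number=1920,
        )
        isolated_area = 4 * np.pi * (radii + params.probe_radius) ** 2
        oracle = sasa / isolated_area
        assert np.max(np.abs(ours - oracle)) < 0.02

    def test_identical_centers_rejected(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            exposed_fractions(coords, np.array([2.0, 2.0]))

    def test_uniform_expansion_unburies_everything(self, dumbbell):
        model, _, _ = dumbbell
        radii = residue_radii(model)
        params = BurialParameters()
        expanded = exposed_fractions(model.coords * 3.0, radii, params)
        report = classify_buried(expanded, model, params)
        assert report.total_buried_volume == 0.0


class TestClassifyBuried:
    def test_all_exposed_gives_zero_volume(self):
        model = _model([[0, 0, 0], [100.0, 0, 0]])
        report = classify_buried(np.array([1.0, 1.0]), model)
        assert report.total_buried_volume == 0.0
        assert not report.buried.any()

    def test_saturating_threshold_buries_everything(self, dumbbell):
        model, dm, _ = dumbbell
        params = BurialParameters(exposure_threshold=1.0 - 1e-9)
        fr = exposed_fractions(model.coords, residue_radii(model, params), params)
        report = classify_buried(fr, model, params, domains=dm)
        vols = residue_volumes(model, params)
        assert report.total_buried_volume == pytest.approx(vols.sum())
        for name, idx in dm.items():
            assert report.domain_buried_volume[name] == pytest.approx(vols[idx].sum())

    def test_domain_sums_bounded_by_total(self, dumbbell):
        model, dm, _ = dumbbell
        report = burial_report(model, domains=dm)
        assert sum(report.domain_buried_volume.values()) <= report.total_buried_volume + 1e-9


class TestEnsembleBurial:
    def test_single_reference_frame_matches_static_report(self, dumbbell_aligned):
        from pullnma.deformation import DeformedEnsemble

        model, dm, _, modes = dumbbell_aligned
        ens = DeformedEnsemble(
            reference=model,
            frames=model.coords[None, :, :].copy(),
            mode_indices=(1,),
            coefficients=np.zeros((1, 1)),
            achieved_rmsd=np.zeros(1),
        )
        stats = ensemble_burial(ens, dm)
        static = burial_report(model, domains=dm)
        summary = stats.summary().set_index("domain")
        for name in dm:
            assert summary.loc[name, "mean_buried_volume"] == pytest.approx(
                static.domain_buried_volume[name]
            )
            assert summary.loc[name, "sd_buried_volume"] == 0.0

    def test_nonzero_restricted_mean_at_least_overall(self, dumbbell_aligned):
        from pullnma import DeformationSpec, sample_ensemble

        model, dm, _, modes = dumbbell_aligned
        spec = DeformationSpec(mode_indices=(6,), target_rmsd=8.0, n_conformations=12, seed=2)
        stats = ensemble_burial(sample_ensemble(modes, spec, reference=model), dm)
        for _, row in stats.summary().iterrows():
            if row["n_nonzero_frames"] > 0:
                assert row["mean_nonzero"] >= row["mean_buried_volume"] - 1e-9

    def test_loose_lobe_buries_less(self):
        """Packing asymmetry built into the fixture shows up as a buried-volume
        asymmetry of the undeformed structure.  Burial is quantized in whole
        residues, so the comparison aggregates a handful of generation seeds."""
        totals = {"lobeA": 0.0, "lobeB": 0.0}
        wins = 0
        seeds = range(5)
        for seed in seeds:
            model, dm, _ = make_dumbbell(
                DumbbellSpec(lobe_packing_radius=(7.8, 10.14), seed=seed)
            )
            report = burial_report(model, domains=dm)
            totals["lobeA"] += report.domain_buried_volume["lobeA"]
            totals["lobeB"] += report.domain_buried_volume["lobeB"]
            wins += report.domain_buried_volume["lobeB"] < report.domain_buried_volume["lobeA"]
        assert totals["lobeB"] < totals["lobeA"]
        assert wins >= len(seeds) - 1
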