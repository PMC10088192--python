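import numpy as np
import pytest
from dataclasses import replace

import qmristats as q
from qmristats.diffusion import fractional_anisotropy, mean_diffusivity
from qmristats.phantom import (
    PhantomError,
    REGIONS,
    axially_symmetric_eigenvalues,
    null_spec,
    tensor_from_md_fa,
)


class TestTensorConstruction:
    @pytest.mark.parametrize(
        "md,fa",
        [(0.7e-3, 0.3), (0.75e-3, 0.0), (1.0e-3, 0.9), (0.5e-3, 0.15)],
    )
    def test_md_fa_round_trip(self, md, fa):
        """Eigendecomposition of the constructed tensor returns the
        requested MD and FA to 1e-12 relative."""
        for direction in ([1, 0, 0], [0, 0, 1], [1, 1, 1], [0.3, -0.5, 0.8]):
            d = tensor_from_md_fa(md, fa, np.asarray(direction, float))
            lam = np.linalg.eigvalsh(d)
            assert mean_diffusivity(lam) == pytest.approx(md, rel=1e-12)
            assert fractional_anisotropy(np.clip(lam, 0, None)) == pytest.approx(fa, rel=1e-12, abs=1e-12)

    def test_principal_axis_aligned(self):
        direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        d = tensor_from_md_fa(0.7e-3, 0.5, direction)
        w, v = np.linalg.eigh(d)
        principal = v[:, np.argmax(w)]
        assert abs(principal @ direction) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("md,fa", [(0.7e-3, 1.0), (0.7e-3, -0.1), (-1e-3, 0.3), (0.0, 0.3)])
    def test_infeasible_pairs_rejected(self, md, fa):
        with pytest.raises(PhantomError):
            axially_symmetric_eigenvalues(md, fa)


class TestDefaultSpec:
    def test_default_acquisition_geometry(self):
        spec = q.default_study_spec()
        assert spec.geometry.shape == (128, 128, 5)
        assert spec.geometry.voxel_size_mm == (0.25, 0.25, 1.5)

    def test_region_sizes_within_window(self):
        spec = q.default_study_spec()
        for reg in spec.regions.values():
            assert 20 <= reg.n_pixels <= 22

    def test_regions_disjoint_and_on_central_slice(self, small_spec):
        labels = small_spec.label_volume()
        counts = {lab: int((labels == lab).sum()) for lab in (1, 2, 3, 4)}
        assert all(20 <= n <= 22 for n in counts.values())
        # everything lives on the designated slice
        other = np.delete(labels, small_spec.central_slice, axis=2)
        assert np.all(other == 0)

    def test_effect_directions(self):
        """The preset encodes the emulated findings: fed tumor T1 lower
        in cortex; control fasted MD lower in cortex; tumor FA lower."""
        spec = q.default_study_spec()
        m = spec.means
        assert m["T1"]["cortex"][("tumor", "fed")] < m["T1"]["cortex"][("control", "fed")]
        assert m["T1"]["thalamus"][("tumor", "fed")] < m["T1"]["thalamus"][("control", "fed")]
        for region in ("cortex", "hippocampus", "thalamus"):
            assert m["MD"][region][("control", "fasted")] < m["MD"][region][("control", "fed")]
            for cond in ("fed", "fasted"):
                assert m["FA"][region][("tumor", cond)] < m["FA"][region][("control", cond)]
        # tumor MD insensitive to condition
        for region in REGIONS:
            assert m["MD"][region][("tumor", "fasted")] == m["MD"][region][("tumor", "fed")]

    def test_overlapping_regions_rejected(self, small_spec):
        regions = dict(small_spec.regions)
        first = regions["cortex"]
        regions["hippocampus"] = replace(regions["hippocampus"], x0=first.x0, y0=first.y0)
        with pytest.raises(PhantomError, match="overlap"):
            replace(small_spec, regions=regions)


class TestMakeStudy:
    def test_deterministic_for_fixed_seed(self, small_spec):
        a = q.make_study(small_spec, seed=3)
        b = q.make_study(small_spec, seed=3)
        assert [x.animal_id for x in a] == [y.animal_id for y in b]
        np.testing.assert_array_equal(a[0].t1_ms, b[0].t1_ms)
        np.testing.assert_array_equal(a[-1].tensor, b[-1].tensor)

    def test_cohort_sizes(self, small_spec):
        animals = q.make_study(small_spec, seed=0)
        from collections import Counter

        counts = Counter((a.state, a.condition) for a in animals)
        assert counts == small_spec.animals_per_group

    def test_zero_noise_gives_exact_group_means(self, small_spec):
        spec = replace(
            small_spec,
            between_animal_sd={"T1": 0.0, "MD": 0.0, "FA": 0.0},
            voxel_cv={"T1": 0.0, "MD": 0.0, "FA": 0.0},
        )
        animal = q.make_study(spec, seed=5)[0]
        reg = spec.regions["cortex"]
        sl = (slice(reg.x0, reg.x0 + reg.nx), slice(reg.y0, reg.y0 + reg.ny), spec.central_slice)
        expected = spec.means["T1"]["cortex"][(animal.state, animal.condition)]
        np.testing.assert_allclose(animal.t1_ms[sl], expected)
        lam = np.linalg.eigvalsh(animal.tensor[sl])
        np.testing.assert_allclose(
            lam.mean(axis=-1), spec.means["MD"]["cortex"][(animal.state, animal.condition)], rtol=1e-10
        )

    def test_voxel_fa_matches_tensor_truth(self, small_spec):
        """FA recomputed from every labelled voxel's tensor stays within
        the configured voxel-level spread of the drawn animal mean."""
        animal = q.make_study(small_spec, seed=9)[0]
        labels = small_spec.label_volume()
        for region, reg in small_spec.regions.items():
            mask = labels == reg.label
            lam = np.linalg.eigvalsh(animal.tensor[mask])
            fa = fractional_anisotropy(np.clip(lam, 0, None))
            target = float(
                animal.region_means.loc[animal.region_means["region"] == region, "FA"].iloc[0]
            )
            spread = 5 * small_spec.voxel_cv["FA"] * max(target, 0.05)
            assert np.all(np.abs(fa - target) < spread + 1e-9)

    def test_labelled_voxels_positive_t1_and_psd_tensor(self, small_spec):
        animal = q.make_study(small_spec, seed=13)[0]
        mask = small_spec.label_volume() > 0
        assert np.all(animal.t1_ms[mask] > 0)
        lam = np.linalg.eigvalsh(animal.tensor[mask])
        assert np.all(lam > -1e-18)

    def test_group_effect_ordering_in_expectation(self, small_geometry):
        """Across many animals the drawn per-animal means respect the
        preset effect directions (population check, 50/group)."""
        spec = q.default_study_spec(
            geometry=small_geometry,
            animals_per_group={(s, c): 50 for s in ("control", "tumor") for c in ("fed", "fasted")},
        )
        animals = q.make_study(spec, seed=21)
        import pandas as pd

        means = pd.concat([a.region_means for a in animals], ignore_index=True)
        g = means.groupby(["state", "condition", "region"])[["T1", "MD", "FA"]].mean()
        assert g.loc[("tumor", "fed", "cortex"), "T1"] < g.loc[("control", "fed", "cortex"), "T1"]
        for region in ("cortex", "hippocampus", "thalamus"):
            assert g.loc[("control", "fasted", region), "MD"] < g.loc[("control", "fed", region), "MD"]
            assert g.loc[("tumor", "fed", region), "FA"] < g.loc[("control", "fed", region), "FA"]


class TestSerialization:
    def test_spec_dict_round_trip(self, small_spec):
        back = q.spec_from_dict(q.spec_to_dict(small_spec))
        assert back == small_spec

    def test_unknown_key_rejected(self, small_spec):
        d = q.spec_to_dict(small_spec)
        d["extra"] = 1
        with pytest.raises(PhantomError, match="extra"):
            q.spec_from_dict(d)

    def test_yaml_round_trip(self, small_spec, tmp_path):
        import yaml

        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(q.spec_to_dict(small_spec)))
        back = q.spec_from_dict(yaml.safe_load(path.read_text()))
        assert back.means == small_spec.means

    def test_truth_maps_written_and_consistent(self, small_spec, tmp_path):
        """Exported ground-truth MD/FA agree with the tensor field."""
        animal = q.make_study(small_spec, seed=2)[0]
        written = q.write_truth_maps(animal, small_spec, tmp_path)
        assert len(written) == 4
        md = q.read_volume(tmp_path / f"{animal.animal_id}_truth_md.nii")
        lam = np.linalg.eigvalsh(animal.tensor)
        np.testing.assert_allclose(md.data, lam.mean(axis=-1), rtol=1e-6)
        t1 = q.read_volume(tmp_path / f"{animal.animal_id}_truth_t1.nii")
        np.testing.assert_allclose(t1.data, animal.t1_ms, rtol=1e-6)


class TestNullSpec:
    def test_removes_group_effects_but_keeps_region_differences(self, small_spec):
        nsp = null_spec(small_spec, "T1")
        for region, cells in nsp.means["T1"].items():
            assert len(set(cells.values())) == 1
        assert len({cells[("control", "fed")] for cells in nsp.means["T1"].values()}) > 1
        # other parameters untouched
        assert nsp.means["MD"] == small_spec.means["MD"]
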