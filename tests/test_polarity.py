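"""Cell-shape and marker polarity metric tests."""

import numpy as np
import pytest

import nichedyn as nd
from nichedyn.polarity import polarity_table
from nichedyn.simulate import TipSphere


class TestRoundness:
    def test_printed_wildtype_ratio(self):
        assert nd.roundness_index(10.0, 4.5) == pytest.approx(0.450)

    def test_sphere_is_one(self):
        assert nd.roundness_index(7.0, 7.0) == 1.0

    def test_axis_ordering_makes_arguments_symmetric(self):
        assert nd.roundness_index(4.5, 10.0) == nd.roundness_index(10.0, 4.5)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError, match="extents"):
            nd.roundness_index(0.0, 3.0)

    def test_unit_rescale_invariance(self):
        assert nd.roundness_index(10.0, 4.5) == \
            pytest.approx(nd.roundness_index(10.0e3, 4.5e3))

    def test_population_mean_recovered_from_generator(self):
        """Generated cohorts with true axis ratio 0.45 yield a recovered
        mean roundness within 2 SE of 0.45."""
        vals = []
        for seed in range(5):
            scene = nd.generate_scene(nd.control_like(n_cells=40, n_frames=12,
                                                      seed=seed))
            t = polarity_table(scene.cell_table)
            vals += t["roundness"].tolist()
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.45) < 2 * se

    def test_axes_from_rendered_ellipsoid_mask(self):
        """Principal-axis extraction recovers the semi-axes of a voxelised
        solid ellipsoid."""
        a, b, c = 6.0, 3.0, 3.0
        n = 17
        zz, yy, xx = np.meshgrid(*[np.arange(n) - 8.0] * 3, indexing="ij")
        mask = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
        length, width = nd.cell_axes_from_mask(mask)
        assert length == pytest.approx(2 * a, rel=0.10)
        assert width == pytest.approx(2 * b, rel=0.10)
        assert nd.roundness_index(length, width) == pytest.approx(0.5, abs=0.05)


class TestGolgiRatio:
    def test_golgi_at_center_is_one(self):
        assert nd.golgi_polarization([0, 0, 5], [0, 0, 5], [0, 0, 0]) == 1.0

    def test_distal_golgi_halves_ratio(self):
        assert nd.golgi_polarization([0, 0, 5], [0, 0, 10], [0, 0, 0]) == \
            pytest.approx(0.5)

    def test_golgi_at_foot_flagged_undefined(self):
        assert np.isnan(nd.golgi_polarization([0, 0, 5], [0, 0, 0],
                                              [0, 0, 0]))

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.4, 0.4, 0.1]).as_matrix()
        pts = np.array([[0, 0, 5.0], [0, 0, 8.0], [0, 0, 0.0]])
        moved = pts @ rot.T + [3.0, 1.0, -2.0]
        assert nd.golgi_polarization(*pts) == \
            pytest.approx(nd.golgi_polarization(*moved))

    def test_distal_population_ratio_below_proximal_in_every_run(self):
        """Cohorts with a distal Golgi offset show a smaller mean a/b ratio
        than unpolarised cohorts in 100 of 100 seeded runs."""
        wins = 0
        for seed in range(100):
            distal = nd.generate_scene(nd.control_like(
                n_cells=15, n_frames=12, golgi_offset=2.0, seed=seed))
            unpol = nd.generate_scene(nd.control_like(
                n_cells=15, n_frames=12, golgi_offset=0.0, seed=seed + 7000))
            rd = polarity_table(distal.cell_table)["golgi_ratio"].mean()
            ru = polarity_table(unpol.cell_table)["golgi_ratio"].mean()
            wins += rd < ru
        assert wins == 100


class TestFoci:
    def test_half_of_distances_beyond_cutoff(self):
        assert nd.foci_far_fraction([1, 3, 6, 10], cutoff=5.0) == 50.0

    def test_foci_on_surface_are_all_near(self):
        assert nd.foci_far_fraction([0.0, 0.0, 0.0]) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nd.foci_far_fraction([])

    def test_monotone_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 15, size=200)
        fracs = [nd.foci_far_fraction(d, cutoff=c) for c in (1, 3, 5, 8, 12)]
        assert all(a >= b for a, b in zip(fracs[:-1], fracs[1:]))

    def test_generator_near_fraction_recovered_binomially(self):
        """desmin_near_fraction 0.8 over 10^3 foci gives a far fraction
        within 3 binomial SE of 20%."""
        scene = nd.generate_scene(nd.control_like(
            n_cells=5, n_frames=12, n_foci=1000, desmin_near_fraction=0.8,
            seed=31))
        d = nd.foci_distances(
            scene.foci[["x_um", "y_um", "z_um"]].to_numpy(), scene.tip(10))
        far = nd.foci_far_fraction(d, cutoff=5.0)
        se = 100 * np.sqrt(0.2 * 0.8 / 1000)
        assert abs(far - 20.0) < 3 * se


class TestNeighborComposition:
    def test_balanced_neighbors_give_ratio_one(self):
        # focal A at origin; 2 A and 2 B neighbours within reach
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                        [-1, 0, 0], [0, -1, 0]], dtype=float)
        types = ["A", "A", "A", "B", "B"]
        out = nd.neighbor_composition(pos, types, touch_distance=0.5,
                                      cell_diameter=1.0)
        assert out[out.cell_index == 0]["ratio"].iloc[0] == pytest.approx(1.0)

    def test_no_heterotypic_neighbors_gives_zero(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0],
                        [0, -1, 0]], dtype=float)
        types = ["A"] * 5
        out = nd.neighbor_composition(pos, types, touch_distance=0.5,
                                      cell_diameter=1.0)
        assert out[out.cell_index == 0]["ratio"].iloc[0] == 0.0

    def test_untyped_cells_rejected(self):
        with pytest.raises(ValueError, match="untyped"):
            nd.neighbor_composition(np.zeros((2, 3)), ["A", "C"])

    def test_isolated_cell_flagged_undefined(self):
        pos = np.array([[0, 0, 0], [50, 0, 0]], dtype=float)
        out = nd.neighbor_composition(pos, ["A", "B"], touch_distance=0.5,
                                      cell_diameter=1.0)
        assert np.isnan(out["ratio"].iloc[0])

    def test_mixed_field_ratio_one_segregated_field_much_less(self):
        """A well-mixed 50/50 field has population mean ratio ~1 (within
        3 SE); a spatially segregated field has mean << 1."""
        rng = np.random.default_rng(17)
        n = 400
        pos = rng.uniform(0, 60, size=(n, 3))
        mixed_types = np.where(rng.random(n) < 0.5, "A", "B")
        out = nd.neighbor_composition(pos, mixed_types, touch_distance=1.0,
                                      cell_diameter=6.0)
        ratios = out["ratio"].dropna()
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se

        seg_types = np.where(pos[:, 0] < 30, "A", "B")
        seg = nd.neighbor_composition(pos, seg_types, touch_distance=1.0,
                                      cell_diameter=6.0)["ratio"].dropna()
        assert seg.mean() < 0.3

    def test_permuted_types_expectation_equals_abundance_ratio(self):
        """Randomly permuting types over fixed positions makes the expected
        per-cell ratio equal the B/A abundance ratio (checked over 10^3
        shuffles)."""
        rng = np.random.default_rng(23)
        n, n_b = 150, 50
        pos = rng.uniform(0, 30, size=(n, 3))
        base = np.array(["A"] * (n - n_b) + ["B"] * n_b)
        means = []
        for _ in range(1000):
            types = rng.permutation(base)
            out = nd.neighbor_composition(pos, types, touch_distance=1.0,
                                          cell_diameter=8.0)
            # pooled ratio: per-cell ratios are Jensen-biased upward, the
            # aggregate neighbour counts are not
            means.append(out["n_other_neighbors"].sum()
                         / out["n_focal_neighbors"].sum())
        means = np.asarray(means)
        # the focal A cell is excluded from its own neighbourhood
        expected = n_b / (n - n_b - 1)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se


class TestTipContacts:
    def test_no_contacting_cells(self):
        tip = TipSphere(np.zeros(3), 10.0)
        pos = np.tile([40.0, 0.0, 0.0], (5, 1))
        out = nd.heterotypic_tip_contacts(pos, ["B"] * 5, [tip],
                                          touch_distance=1.0, cell_radius=4.0)
        assert out["n_contacts"].iloc[0] == 0

    def test_cells_on_surface_counted(self):
        tip = TipSphere(np.zeros(3), 10.0)
        pos = np.tile([10.0, 0.0, 0.0], (3, 1))
        out = nd.heterotypic_tip_contacts(pos, ["B"] * 3, [tip],
                                          touch_distance=1.0, cell_radius=0.0)
        assert out["n_contacts"].iloc[0] == 3

    def test_no_domains_rejected(self):
        with pytest.raises(ValueError, match="domains"):
            nd.heterotypic_tip_contacts(np.zeros((1, 3)), ["B"], [])

    def test_fourfold_infiltration_recovered_over_domains(self):
        """Scenes with 4x the near-tip secondary-cell fraction show a
        ~4-fold higher mean per-domain contact count (within 2 SE) over 30
        simulated tip domains."""
        counts = {0.1: [], 0.4: []}
        for frac, store in counts.items():
            for k in range(30):
                scene = nd.generate_scene(nd.control_like(
                    n_cells=5, n_frames=12, n_secondary=40,
                    secondary_near_fraction=frac, seed=500 + k))
                pos = scene.secondary[["x_um", "y_um", "z_um"]].to_numpy()
                out = nd.heterotypic_tip_contacts(
                    pos, ["B"] * len(pos), [scene.tip(10)],
                    touch_distance=0.5, cell_radius=0.0)
                store.append(out["n_contacts"].iloc[0])
        lo = np.asarray(counts[0.1], dtype=float)
        hi = np.asarray(counts[0.4], dtype=float)
        fold = hi.mean() / lo.mean()
        se_fold = fold * np.sqrt(lo.var(ddof=1) / (30 * lo.mean() ** 2)
                                 + hi.var(ddof=1) / (30 * hi.mean() ** 2))
        # the generator rounds the near-tip count, so replicate variance
        # can legitimately be zero
        assert abs(fold - 4.0) <= max(2 * se_fold, 1e-9)
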