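"""Generator ground truth: determinism, moments, latent structure."""

import numpy as np
import pandas as pd
import pytest

import spherovar as sv
from spherovar import preprocess
from spherovar.synthetic import MarkerSpec, SyntheticConfig
from spherovar.decomposition import spline_basis
from conftest import attach_values, build_graph


SMALL = dict(n_spheres=3, slices_per_sphere=2, sphere_radius_mean=70.0)


def test_seeded_determinism_is_byte_identical():
    cfg = SyntheticConfig(**SMALL)
    a, _ = sv.generate_condition(cfg, 9)
    b, _ = sv.generate_condition(cfg, 9)
    pd.testing.assert_frame_equal(a, b)


def test_more_spheres_do_not_reshuffle_existing_ones():
    # per-sphere substreams: geometry and latent draws of existing spheres
    # are unchanged when spheres are added (marker values do shift, since
    # latent standardization pools over the whole condition)
    a, ta = sv.generate_condition(SyntheticConfig(**SMALL), 9)
    b, tb = sv.generate_condition(SyntheticConfig(**{**SMALL, "n_spheres": 5}), 9)
    keep = b["sphere_id"].isin(a["sphere_id"].unique())
    first = b[keep].reset_index(drop=True)
    geom = ["sphere_id", "image_id", "pos_x", "pos_y", "area", "dist_border", "r_real"]
    pd.testing.assert_frame_equal(a[geom], first[geom])
    # unstandardized white draws match too
    la, lb = ta.latents, tb.latents.loc[keep.to_numpy()].reset_index(drop=True)
    assert np.allclose(la["u3_0"], lb["u3_0"])


def test_degenerate_marker_is_function_of_distance_within_image():
    panel = [MarkerSpec("pure", "signaling", w1=0.5, noise_sd=0.0, w3=())]
    cfg = SyntheticConfig(markers=panel, image_offset_sd=0.3, **SMALL)
    cells, _ = sv.generate_condition(cfg, 3)
    z = np.log10(cells["raw_pure"] + 0.1)
    for _, grp in cells.groupby("image_id"):
        # within an image, z = baseline + w1·u1(d) + b_i exactly
        zg = z[grp.index]
        order = np.argsort(grp["r_real"].to_numpy())
        assert np.all(np.diff(zg.to_numpy()[order]) <= 1e-12)  # monotone_out shape


def test_pure_noise_moments():
    panel = [MarkerSpec("noise", "other", noise_sd=1.0, w3=(), baseline=2.0)]
    cfg = SyntheticConfig(markers=panel, image_offset_sd=0.3,
                          n_spheres=5, slices_per_sphere=5, sphere_radius_mean=110.0)
    cells, truth = sv.generate_condition(cfg, 4)
    assert len(cells) > 4000
    z = np.log10(cells["raw_noise"] + 0.1)
    for img, grp in cells.groupby("image_id"):
        b = truth.image_offsets[img]
        n = len(grp)
        assert z[grp.index].mean() == pytest.approx(2.0 + b, abs=4.0 / np.sqrt(n))
    within = z - cells["image_id"].map(z.groupby(cells["image_id"]).mean())
    assert within.var() == pytest.approx(1.0, abs=0.05)


def test_transform_inverts_generator_exactly():
    # raw = max(0, 10^z - 0.1), so log10(raw + 0.1) recovers z wherever
    # z >= -1; a noise-free marker makes z fully reconstructable
    panel = [MarkerSpec("clean", "signaling", w1=0.4, noise_sd=0.0, w3=(), baseline=1.0)]
    cfg2 = SyntheticConfig(markers=panel, image_offset_sd=0.0, **SMALL)
    cells2, truth2 = sv.generate_condition(cfg2, 6)
    z2 = 1.0 + 0.4 * truth2.latents["u1_monotone_out"]
    rec2 = np.log10(cells2["raw_clean"] + 0.1)
    ok2 = z2 >= -1
    assert np.allclose(rec2[ok2], z2[ok2], atol=1e-12)


def test_u2_autocorrelation_increases_with_smoothing():
    prev = -np.inf
    for steps in (0, 1, 3, 6):
        vals = []
        for seed in range(5):
            cfg = SyntheticConfig(smoothing_steps=steps, **SMALL)
            cells, truth = sv.generate_condition(cfg, seed)
            graph = build_graph(cells, cfg)
            u2 = truth.latents["u2"].to_numpy()
            nm = graph.neighbor_mean(u2)
            ok = ~np.isnan(nm)
            vals.append(np.corrcoef(u2[ok], nm[ok])[0, 1])
        cur = float(np.mean(vals))
        assert cur > prev
        prev = cur


def test_gradient_marker_has_no_neighbor_signal_beyond_distance():
    # w1-only marker: partial correlation with neighbor means given the
    # distance spline should vanish
    panel = [MarkerSpec("grad", "signaling", w1=0.5, noise_sd=0.3, w3=())]
    cfg = SyntheticConfig(markers=panel, n_spheres=5, slices_per_sphere=5,
                          sphere_radius_mean=110.0)
    cells, _ = sv.generate_condition(cfg, 8)
    assert len(cells) >= 4000
    attach_values(cells, ["grad"])
    graph = build_graph(cells, cfg)
    y = cells["value_grad"].to_numpy()
    nb = graph.neighbor_mean(y)
    ok = ~np.isnan(nb)
    X = spline_basis(cells.loc[ok, "r_real"].to_numpy())
    img = pd.get_dummies(cells.loc[ok, "image_id"]).to_numpy(float)
    D = np.column_stack([X, img])
    ry = y[ok] - D @ np.linalg.lstsq(D, y[ok], rcond=None)[0]
    rn = nb[ok] - D @ np.linalg.lstsq(D, nb[ok], rcond=None)[0]
    r = np.corrcoef(ry, rn)[0, 1]
    assert abs(r) < 0.05


def test_slices_have_min_cells():
    cfg = SyntheticConfig(**SMALL)
    cells, _ = sv.generate_condition(cfg, 1)
    assert (cells.groupby("image_id").size() >= cfg.min_cells_per_slice).all()


class TestPerturbation:
    EFFECTS = pd.DataFrame(
        [{"construct": "E0", "marker": "pS6", "class": "oexp",
          "log10_effect": np.log10(1.5)}]
    )

    def test_zero_effects_equal_null_generation(self):
        cfg = SyntheticConfig(**SMALL)
        zero = self.EFFECTS.assign(log10_effect=0.0)
        a, _ = sv.generate_perturbation(cfg, zero, seed=2, spheres_per_construct=2,
                                        mock_spheres=2)
        b, _ = sv.generate_perturbation(cfg, self.EFFECTS.iloc[:0], seed=2,
                                        constructs=["E0"], spheres_per_construct=2,
                                        mock_spheres=2)
        pd.testing.assert_frame_equal(a, b)

    def test_injected_effect_recovered_by_group_means(self):
        cells, truth = sv.generate_perturbation(
            sv.perturbation_config(markers=[
                MarkerSpec("pS6", "signaling", w1=0.0, noise_sd=0.2, w3=())
            ]),
            self.EFFECTS, seed=3, spheres_per_construct=12, mock_spheres=12,
        )
        v = np.log10(cells["raw_pS6"] + 0.1)
        oexp = v[(cells["construct"] == "E0") & (cells["true_class"] == "oexp")]
        mock = v[cells["construct"] == "mock"]
        assert len(oexp) > 400
        assert oexp.mean() - mock.mean() == pytest.approx(np.log10(1.5), abs=0.03)

    def test_target_fraction_realized(self):
        cfg = SyntheticConfig(**SMALL)
        cells, _ = sv.generate_perturbation(
            cfg, self.EFFECTS.iloc[:0], seed=4, constructs=["E0"],
            spheres_per_construct=3, mock_spheres=1, target_fraction=0.2,
        )
        sub = cells[cells["construct"] == "E0"]
        frac = sub.groupby("sphere_id").apply(
            lambda g: (g["true_class"] == "oexp").mean(), include_groups=False
        )
        assert ((frac >= 0.1) & (frac <= 0.3)).all()

    def test_unknown_marker_rejected(self):
        cfg = SyntheticConfig(**SMALL)
        bad = self.EFFECTS.assign(marker="nope")
        with pytest.raises(ValueError):
            sv.generate_perturbation(cfg, bad, seed=1)

    def test_mock_spheres_receive_no_effects(self):
        cfg = SyntheticConfig(**SMALL)
        cells, truth = sv.generate_perturbation(
            cfg, self.EFFECTS, seed=5, spheres_per_construct=2, mock_spheres=2
        )
        assert (cells.loc[cells["construct"] == "mock", "true_class"] == "bystander").all()
        assert (cells.loc[cells["construct"] == "mock", "oe_score"] < 0.01).all()


def test_truth_shares_sum_to_one():
    cfg = SyntheticConfig(**SMALL)
    _, truth = sv.generate_condition(cfg, 1)
    total = truth.shares[["dist", "nb", "self", "src", "int", "noise"]].sum(axis=1)
    assert np.allclose(total, 1.0)
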