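"""Sampling core: Dirichlet weights (closed-form moments), mix-blend
convexity and corner limits, multi-blend enumeration, stream determinism
and coverage, precompute layout and loader consistency."""

import numpy as np
import pytest

from chromablend import (
    ContractError,
    StreamConfig,
    blend_trivial,
    draw_mix_weights,
    load_precomputed,
    make_rng,
    mix_blend,
    multi_blend,
    precompute_dataset,
    sample_stream,
)
from chromablend.blending import BASIS_ORDER, basis_blends


class TestDrawMixWeights:
    def test_single_component_is_degenerate(self):
        w = draw_mix_weights((2.5,), make_rng(0, "l"))
        assert w.lam.shape == (1,) and w.lam[0] == 1.0

    def test_uniform_alpha_moments_match_closed_form(self):
        rng = make_rng(123, "lambda")
        draws = np.array([draw_mix_weights((1.0, 1.0, 1.0), rng).lam for _ in range(10_000)])
        # Dir(1,1,1): E[λ_m] = 1/3, Var[λ_m] = α(α0−α)/(α0²(α0+1)) = 2/36 = 1/18
        var = 1.0 / 18.0
        se_mean = np.sqrt(var / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 1.0 / 3.0) <= 3 * se_mean)
        sample_var = draws[:, 0].var(ddof=1)
        m4 = np.mean((draws[:, 0] - draws[:, 0].mean()) ** 4)
        se_var = np.sqrt(max(m4 - sample_var**2, 0.0) / 10_000)
        assert abs(sample_var - var) <= 3 * se_var

    def test_tiny_alpha_concentrates_at_simplex_corners(self):
        # the true corner rate is ~0.991; 100k draws keep the Monte Carlo
        # error well below the 0.001 margin over the 0.99 bound
        rng = make_rng(7, "lambda")
        maxima = [
            draw_mix_weights((0.001, 0.001, 0.001), rng).lam.max()
            for _ in range(100_000)
        ]
        assert np.mean(np.asarray(maxima) > 0.99) >= 0.99

    def test_weights_strictly_positive_and_normalized(self):
        rng = make_rng(9, "lambda")
        for _ in range(200):
            w = draw_mix_weights((0.001, 0.5, 3.0), rng)
            assert np.all(w.lam > 0)
            assert abs(w.lam.sum() - 1.0) <= 1e-9

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ContractError):
            draw_mix_weights((1.0, 0.0, 1.0), make_rng(0, "l"))


class TestMixBlend:
    def test_corner_limit_matches_trivial_blend(self, fg_sample, bg_sample):
        eps = 1e-6
        from chromablend.composer import MixWeights

        w = MixWeights(
            lam=np.array([1 - 2 * eps, eps, eps]), alpha=np.ones(3)
        )
        comp = mix_blend(fg_sample, bg_sample, w)
        trivial = blend_trivial(fg_sample, bg_sample)
        assert np.abs(comp.image - trivial.image).max() <= 3e-6

    def test_weighted_sum_arithmetic(self):
        # basis outputs (0.2, 0.6, 0.6) with λ=(0.5, 0.25, 0.25) -> 0.4
        lam = np.array([0.5, 0.25, 0.25])
        vals = np.array([0.2, 0.6, 0.6])
        assert float(lam @ vals) == pytest.approx(0.4)

    def test_convex_hull_property_per_pixel(self, fg_pool, bg_pool):
        rng = make_rng(11, "hull")
        for trial in range(5):
            fg = fg_pool[trial % len(fg_pool)]
            bg = bg_pool[trial % len(bg_pool)]
            basis = basis_blends(fg, bg)
            w = draw_mix_weights((1.0, 1.0, 1.0), rng)
            stack = np.stack([b.image for b in basis])
            mixed = np.tensordot(w.lam, stack, axes=(0, 0))  # pre-clipping
            assert np.all(mixed >= stack.min(axis=0) - 1e-12)
            assert np.all(mixed <= stack.max(axis=0) + 1e-12)

    def test_label_independent_of_lambda(self, fg_sample, bg_sample):
        rng = make_rng(13, "lam")
        labels = [
            mix_blend(fg_sample, bg_sample, draw_mix_weights((1, 1, 1), rng)).label
            for _ in range(10)
        ]
        for lab in labels:
            assert np.array_equal(lab, fg_sample.mask)


class TestMultiBlend:
    def test_enumeration_count(self, fg_pool, bg_pool):
        composites = [
            c for fg in fg_pool[:2] for bg in bg_pool[:2] for c in multi_blend(fg, bg)
        ]
        assert len(composites) == 2 * 2 * len(BASIS_ORDER) == 12

    def test_labels_identical_across_modes(self, fg_sample, bg_sample):
        comps = multi_blend(fg_sample, bg_sample)
        for c in comps:
            assert np.array_equal(c.label, comps[0].label)

    def test_provenance_records_mode(self, fg_sample, bg_sample):
        modes = [c.provenance["blend"] for c in multi_blend(fg_sample, bg_sample)]
        assert modes == list(BASIS_ORDER)


class TestSampleStream:
    def test_same_seed_reproduces_samples_exactly(self, fg_pool, bg_pool):
        cfg = StreamConfig(n_iterations=10, seed=77)
        a = list(sample_stream(fg_pool, bg_pool, cfg))
        b = list(sample_stream(fg_pool, bg_pool, cfg))
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert np.array_equal(x.label, y.label)
            assert x.provenance == y.provenance

    def test_every_pair_visited_in_long_stream(self, fg_pool, bg_pool):
        cfg = StreamConfig(n_iterations=1000, seed=5, apply_augment=False)
        seen = set()
        for comp in sample_stream(fg_pool, bg_pool, cfg):
            seen.add((comp.provenance["fg_id"], comp.provenance["bg_id"]))
        assert len(seen) == len(fg_pool) * len(bg_pool)

    def test_lambda_draws_are_distinct(self, fg_pool, bg_pool):
        cfg = StreamConfig(n_iterations=50, seed=6, apply_augment=False)
        lams = [tuple(c.provenance["blend"]) for c in sample_stream(fg_pool, bg_pool, cfg)]
        assert len(set(lams)) == len(lams)

    def test_empty_sources_rejected(self, bg_pool):
        with pytest.raises(ContractError):
            next(sample_stream([], bg_pool, StreamConfig()))

    def test_single_mode_stream_emits_that_basis(self, fg_pool, bg_pool):
        cfg = StreamConfig(n_iterations=3, seed=8, mode="laplacian", apply_augment=False)
        for comp in sample_stream(fg_pool, bg_pool, cfg):
            assert comp.provenance["blend"] == "laplacian"


class TestPrecompute:
    def test_layout_counts(self, fg_pool, bg_pool, tmp_path):
        cfg = StreamConfig(n_iterations=10, seed=3, apply_augment=False)
        manifest = precompute_dataset(fg_pool, bg_pool, 10, cfg, tmp_path)
        basis_images = [
            p for p in tmp_path.glob("sample-*.png") if not p.stem.endswith("_mask")
        ]
        masks = list(tmp_path.glob("sample-*_mask.png"))
        assert len(basis_images) == 10 * 3
        assert len(masks) == 10
        assert (tmp_path / "manifest.json").exists()
        assert len(manifest.records) == 10

    def test_loader_corner_limit_recovers_trivial_image(self, fg_pool, bg_pool, tmp_path):
        cfg = StreamConfig(n_iterations=2, seed=4, apply_augment=False)
        precompute_dataset(fg_pool, bg_pool, 2, cfg, tmp_path)
        comp = load_precomputed(
            tmp_path, "sample-000000", (1e4, 1e-4, 1e-4), make_rng(0, "load")
        )
        from chromablend import read_image

        stored = read_image(tmp_path / "sample-000000_trivial.png")
        assert np.abs(comp.image - stored).max() <= 1.5 / 255.0

    def test_rerun_same_seed_identical_manifest_bytes(self, fg_pool, bg_pool, tmp_path):
        cfg = StreamConfig(n_iterations=5, seed=9, apply_augment=False)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        precompute_dataset(fg_pool, bg_pool, 5, cfg, d1)
        precompute_dataset(fg_pool, bg_pool, 5, cfg, d2)
        assert (d1 / "manifest.json").read_bytes() == (d2 / "manifest.json").read_bytes()
        for p in sorted(d1.glob("*.png")):
            assert p.read_bytes() == (d2 / p.name).read_bytes()
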