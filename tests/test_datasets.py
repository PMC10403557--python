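"""Preprocessing, splits, shortcut injection, and manifest round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adadetect import (
    ADASpec,
    LabeledDataset,
    PhantomSpec,
    PreprocessSpec,
    build_detective_trainset,
    equal_random_split,
    generate_labeled_dataset,
    inject_into_class,
    read_manifest,
    window_and_quantize,
    write_manifest,
)
from adadetect.ada import gradient_energy


class TestWindowAndQuantize:
    def test_window_endpoints_clip(self):
        spec = PreprocessSpec(window_center=1000, window_width=400, out_size=8)
        raw = np.full((8, 8), 800.0)  # center - width/2
        assert np.all(window_and_quantize(raw, spec) == 0)
        raw = np.full((8, 8), 1300.0)  # above center + width/2
        assert np.all(window_and_quantize(raw, spec) == 255)

    def test_center_maps_to_128(self):
        # 255 * 0.5 = 127.5 rounds half-away-from-zero to 128
        for width in (10.0, 400.0, 4096.0):
            spec = PreprocessSpec(window_center=50.0, window_width=width, out_size=8)
            raw = np.full((8, 8), 50.0)
            assert np.all(window_and_quantize(raw, spec) == 128)

    @pytest.mark.parametrize("out_size", [8, 16, 50])
    def test_constant_raster_stays_constant_at_any_size(self, out_size):
        spec = PreprocessSpec(window_center=127.5, window_width=255.0,
                              out_size=out_size)
        out = window_and_quantize(np.full((33, 21), 60.0), spec)
        assert out.shape == (out_size, out_size)
        assert np.all(out == 60)

    def test_idempotent_on_8bit_full_range_window(self):
        img = np.random.default_rng(0).integers(0, 256, (32, 32)).astype(np.uint8)
        spec = PreprocessSpec(window_center=127.5, window_width=255.0, out_size=32)
        once = window_and_quantize(img.astype(float), spec)
        assert np.array_equal(once, img)
        assert np.array_equal(window_and_quantize(once.astype(float), spec), once)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            PreprocessSpec(window_width=0.0)


class TestEqualRandomSplit:
    def test_full_scale_pool_halves_exactly(self):
        a, b = equal_random_split(46894, seed=0)
        assert len(a) == 23447 and len(b) == 23447

    @given(n=st.integers(2, 1000), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_disjoint_exhaustive_balanced(self, n, seed):
        a, b = equal_random_split(n, seed)
        assert len(a) == (n + 1) // 2 and len(b) == n // 2
        assert len(np.intersect1d(a, b)) == 0
        assert np.array_equal(np.sort(np.concatenate([a, b])), np.arange(n))

    def test_deterministic_and_seed_sensitive(self):
        assert all(
            np.array_equal(x, y)
            for x, y in zip(equal_random_split(1000, 3), equal_random_split(1000, 3))
        )
        a1, _ = equal_random_split(1000, 3)
        a2, _ = equal_random_split(1000, 4)
        assert not np.array_equal(a1, a2)

    def test_rejects_n_below_two(self):
        with pytest.raises(ValueError):
            equal_random_split(1, seed=0)


class TestBuildTrainset:
    def test_split_sizes_and_provenance(self, pool600):
        ada = ADASpec("contrast", gamma=1.3)
        ts = build_detective_trainset(pool600.images[:100], ada, seed=1)
        assert ts.n_pos == 50 and ts.n_neg == 50
        assert ts.injected_ada == (ada, 1)

    def test_identity_spec_leaves_positives_bitidentical(self, pool600):
        ada = ADASpec("contrast", gamma=1.0)
        imgs = pool600.images[:40]
        ts = build_detective_trainset(imgs, ada, seed=2)
        assert all(np.array_equal(a, b) for a, b in zip(ts.images, imgs))

    def test_negatives_untouched_by_injection(self, pool600):
        ada = ADASpec("sharpness", blur_sigma=1.0)
        imgs = pool600.images[:40]
        ts = build_detective_trainset(imgs, ada, seed=3)
        for orig, out, lbl in zip(imgs, ts.images, ts.labels):
            if lbl == 0:
                assert np.array_equal(orig, out)
            else:
                assert not np.array_equal(orig, out)

    def test_contrast_injection_shifts_class_mean(self):
        # with gamma=1.3 the positive-class mean intensity must separate from
        # the negative class by well over 3 standard errors at n=500
        pool = generate_labeled_dataset(500, PhantomSpec(), seed=77)
        ts = build_detective_trainset(pool.images, ADASpec("contrast", gamma=1.3),
                                      seed=78)
        vals = np.array([img.mean() for img in ts.images])
        a, b = vals[ts.labels == 1], vals[ts.labels == 0]
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) > 3 * se

    def test_rejects_mixed_sizes(self):
        imgs = [np.zeros((8, 8), np.uint8), np.zeros((9, 9), np.uint8)]
        with pytest.raises(ValueError, match="mixed"):
            build_detective_trainset(imgs, ADASpec("contrast", gamma=1.3), seed=0)


class TestInjectIntoClass:
    def test_only_target_class_changes(self, pool600):
        ds = LabeledDataset(images=pool600.images[:60],
                            labels=pool600.labels[:60])
        out = inject_into_class(ds, ADASpec("sharpness", blur_sigma=1.0), 1)
        for orig, new, lbl in zip(ds.images, out.images, ds.labels):
            if lbl == 1:
                assert not np.array_equal(orig, new)
            else:
                assert np.array_equal(orig, new)
        assert out.injected_ada is not None

    def test_double_injection_forbidden(self, pool600):
        ds = LabeledDataset(images=pool600.images[:20],
                            labels=pool600.labels[:20])
        ada = ADASpec("sharpness", blur_sigma=1.0)
        once = inject_into_class(ds, ada, 1)
        with pytest.raises(ValueError, match="double injection"):
            inject_into_class(once, ada, 0)

    def test_blur_direction_flips_gradient_energy_gap(self, pool600):
        ds = LabeledDataset(images=pool600.images[:200],
                            labels=pool600.labels[:200])
        ada = ADASpec("sharpness", blur_sigma=1.0)

        def gap(injected):
            vals = np.array([gradient_energy(i) for i in injected.images])
            return vals[injected.labels == 1].mean() - vals[injected.labels == 0].mean()

        assert gap(inject_into_class(ds, ada, 1)) < 0 < gap(inject_into_class(ds, ada, 0))


class TestManifestIO:
    def test_round_trip(self, tmp_path, pool600):
        ds = LabeledDataset(
            images=pool600.images[:5],
            labels=pool600.labels[:5],
            patient_ids=[f"PT{i}" for i in range(5)],
            name="rt",
        )
        manifest = write_manifest(ds, tmp_path / "d")
        back = read_manifest(manifest)
        assert len(back) == 5
        assert np.array_equal(back.labels, ds.labels)
        assert back.patient_ids == ds.patient_ids
        assert all(np.array_equal(a, b) for a, b in zip(back.images, ds.images))

    def test_provenance_round_trip(self, tmp_path, pool600):
        ada = ADASpec("contrast", gamma=1.3)
        ts = build_detective_trainset(pool600.images[:10], ada, seed=4)
        manifest = write_manifest(ts, tmp_path / "d")
        back = read_manifest(manifest)
        assert back.injected_ada == (ada, 1)

    def test_unknown_label_names_the_row(self, tmp_path, pool600):
        manifest = write_manifest(
            LabeledDataset(images=pool600.images[:3], labels=[0, 1, 0]),
            tmp_path / "d",
        )
        df = pd.read_csv(manifest)
        df.loc[1, "label"] = 2
        df.to_csv(manifest, index=False)
        with pytest.raises(ValueError, match="rows: 3"):
            read_manifest(manifest)

    def test_missing_file_is_an_error(self, tmp_path, pool600):
        manifest = write_manifest(
            LabeledDataset(images=pool600.images[:3], labels=[0, 1, 0]),
            tmp_path / "d",
        )
        (tmp_path / "d" / "images" / "000001.png").unlink()
        with pytest.raises(FileNotFoundError):
            read_manifest(manifest)
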