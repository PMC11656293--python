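"""Dark/pulse sorting, hot-pixel repair and background subtraction."""

import dataclasses

import numpy as np
import pytest

from scintqa.preprocess import (
    DarkModel,
    build_dark_model,
    classify_frames,
    preprocess_stack,
    repair_hot_pixels,
    subtract_background,
)
from scintqa.simulate import DeliveryConfig, FrameStack, deliver, render


def _flood_fill_has_big_cluster(mask: np.ndarray, min_cluster: int) -> bool:
    """Brute-force 8-connected flood fill: any component strictly larger than
    min_cluster?"""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, size = [(r0, c0)], 0
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if size > min_cluster:
                return True
    return False


def _stack(frames: np.ndarray) -> FrameStack:
    return FrameStack(
        pixels=frames.astype(np.uint16),
        timestamps=np.arange(len(frames), dtype=float),
    )


class TestClassifyFrames:
    def test_matches_flood_fill_oracle_on_random_stack(self):
        rng = np.random.default_rng(0)
        h, w, sd = 24, 32, 3.0
        frames = np.clip(rng.normal(50.0, sd, size=(50, h, w)), 0, 300)
        # give ~half the frames a blob of random area around the threshold
        for k in range(0, 50, 2):
            rr, cc = rng.integers(4, h - 8), rng.integers(4, w - 8)
            a = rng.integers(3, 12)
            frames[k, rr:rr + a, cc:cc + a] += 40.0
        dark = DarkModel(np.full((h, w), 50.0), sd, 5)
        min_cluster = 40
        stack = _stack(frames)
        pulse_idx, dark_idx = classify_frames(stack, dark, min_cluster)
        assert len(pulse_idx) + len(dark_idx) == len(stack)
        assert set(pulse_idx).isdisjoint(dark_idx)
        for k in range(len(stack)):
            sub = stack.pixels[k].astype(float) - dark.mean_image
            expect = _flood_fill_has_big_cluster(sub > sd, min_cluster)
            assert (k in pulse_idx) == expect

    def test_cluster_of_exactly_min_cluster_is_dark(self):
        h, w = 32, 32
        frame = np.full((h, w), 50.0)
        frame[5:10, 5:15] += 30.0  # 5 x 10 = exactly 50 pixels
        dark = DarkModel(np.full((h, w), 50.0), 2.0, 5)
        pulse_idx, _ = classify_frames(_stack(frame[None]), dark, min_cluster=50)
        assert len(pulse_idx) == 0
        frame[10, 5] += 30.0  # 51st pixel, 8-connected to the block
        pulse_idx, _ = classify_frames(_stack(frame[None]), dark, min_cluster=50)
        assert len(pulse_idx) == 1

    def test_pure_noise_stack_has_no_pulse_frames(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(100.0, 2.0, size=(30, 32, 40))
        dark = DarkModel(np.full((32, 40), 100.0), 2.0, 5)
        pulse_idx, dark_idx = classify_frames(_stack(frames), dark)
        assert len(pulse_idx) == 0 and len(dark_idx) == 30

    def test_empty_stack_rejected(self):
        dark = DarkModel(np.zeros((4, 4)), 1.0, 1)
        with pytest.raises(ValueError):
            classify_frames(
                FrameStack(np.empty((0, 4, 4), dtype=np.uint16), np.empty(0)),
                dark,
            )


class TestHotPixels:
    def test_single_isolated_spike_repaired(self):
        img = np.full((21, 21), 100.0)
        img[10, 10] = 1e4
        out, n = repair_hot_pixels(img, dark_sd=5.0)
        assert n == 1
        assert out[10, 10] == pytest.approx(100.0)

    def test_smooth_blob_untouched(self):
        r, c = np.mgrid[0:41, 0:41]
        img = 100.0 + 5000.0 * np.exp(-((r - 20) ** 2 + (c - 20) ** 2) / (2 * 36.0))
        out, n = repair_hot_pixels(img, dark_sd=5.0)
        assert n == 0
        assert np.array_equal(out, img)

    def test_mass_injection_over_rendered_frame(self, geom_half_clean,
                                                small_delivery):
        cfg, pulses = small_delivery
        stack = render(pulses[:1], geom_half_clean, cfg)
        img = stack.pixels[0].astype(float)
        peak_before = np.unravel_index(np.argmax(img), img.shape)
        rng = np.random.default_rng(3)
        # 100 isolated positions (>= 3 px apart, away from the injected peak)
        taken: list[tuple[int, int]] = []
        while len(taken) < 100:
            r = int(rng.integers(2, img.shape[0] - 2))
            c = int(rng.integers(2, img.shape[1] - 2))
            if all(abs(r - rr) > 2 or abs(c - cc) > 2 for rr, cc in taken) \
                    and (r, c) != peak_before:
                taken.append((r, c))
        for r, c in taken:
            img[r, c] = 5e4
        out, n = repair_hot_pixels(img, dark_sd=10.0)
        assert n >= 99
        assert np.unravel_index(np.argmax(out), out.shape) == peak_before
        out2, n2 = repair_hot_pixels(out, dark_sd=10.0)
        assert n2 == 0  # idempotent


class TestBackground:
    BOUNDS = dict(direct_bounds=(2, 30, 40, 68), mirror_bounds=(4, 28, 12, 36))

    def test_dark_plus_row_constant_cancels_exactly(self):
        rng = np.random.default_rng(0)
        dark_img = rng.uniform(90.0, 110.0, size=(32, 70))
        dark = DarkModel(dark_img, 2.0, 5)
        row_c = rng.uniform(-5.0, 5.0, size=(32, 1))
        image = dark_img + row_c
        clean = subtract_background(image, dark, margin=8, **self.BOUNDS)
        assert np.allclose(clean.pixels, 0.0, atol=1e-9)

    def test_row_drift_removed_to_noise_level(self):
        rng = np.random.default_rng(1)
        h, w, sd = 32, 70, 2.0
        dark = DarkModel(np.full((h, w), 100.0), sd, 5)
        drift = np.linspace(0, 10, h)[:, None]  # row-wise ramp
        image = 100.0 + drift + rng.normal(0, sd, size=(h, w))
        clean = subtract_background(image, dark, margin=8, **self.BOUNDS)
        assert np.all(np.abs(clean.pixels.mean(axis=1)) < sd)

    def test_blob_integral_preserved(self):
        h, w = 32, 70
        dark = DarkModel(np.full((h, w), 100.0), 2.0, 5)
        r, c = np.mgrid[0:h, 0:w]
        blob = 500.0 * np.exp(-((r - 16) ** 2 + (c - 54) ** 2) / (2 * 9.0))
        image = 100.0 + np.linspace(0, 5, h)[:, None] + blob
        clean = subtract_background(image, dark, margin=8, **self.BOUNDS)
        region = (slice(8, 25), slice(45, 64))
        assert clean.pixels[region].sum() == pytest.approx(
            blob[region].sum(), rel=1e-3
        )

    def test_margin_overlapping_view_rejected(self):
        dark = DarkModel(np.full((32, 70), 100.0), 2.0, 5)
        with pytest.raises(ValueError):
            subtract_background(np.zeros((32, 70)), dark, margin=20, **self.BOUNDS)


class TestEndToEnd:
    def test_partition_and_manifest(self, geom_half, small_delivery):
        cfg, pulses = small_delivery
        stack = render(pulses[:30], geom_half, cfg)
        cleaned, manifest, dark = preprocess_stack(stack, geom_half)
        assert len(manifest) == len(stack)
        assert (manifest["class"] == "pulse").sum() == len(cleaned)
        # every true pulse trigger recovered, no dark misclassified
        assert len(cleaned) == stack.metadata["n_pulse_triggers"]

    def test_amplitude_rank_order_preserved(self, geom_half_clean):
        from scintqa.simulate import PulseRecord

        intensities = [0.002, 0.01, 0.05, 0.02, 0.1]
        pulses = [
            PulseRecord(float(k), 0.0, 0.0, 140.0, I, k, 0, 0)
            for k, I in enumerate(intensities)
        ]
        cfg = DeliveryConfig(rng_seed=0, dark_frame_fraction=0.0)
        stack = render(pulses, geom_half_clean, cfg)
        # no dark triggers in this stack: provide the (exact) dark model
        dark = DarkModel(
            np.full(geom_half_clean.sensor_shape, geom_half_clean.pedestal), 1.0, 1
        )
        cleaned, _, _ = preprocess_stack(stack, geom_half_clean, dark=dark)
        assert len(cleaned) == 5
        amps = [c.direct_view().max() for c in cleaned]
        assert np.argsort(amps).tolist() == np.argsort(intensities).tolist()
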