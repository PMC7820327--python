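"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from uwfdr import field_geometry as fg
from uwfdr import landmarks as lmk
from uwfdr import od_unet as odu
from uwfdr import synthetic as syn


@pytest.fixture(scope="session")
def ref_pairs():
    """Reference (image, disc mask) pairs for threshold estimation."""
    pairs = []
    rng = np.random.default_rng(4242)
    for i in range(12):
        spec = syn.make_spec(seed=int(rng.integers(2 ** 31)),
                             laterality="OD" if i % 2 else "OS")
        img, _ = syn.generate_fundus(spec)
        mask = syn.ellipse_mask(img.shape[:2], spec.disc_center, spec.disc_axes,
                                spec.disc_angle)
        pairs.append((img, mask))
    return pairs


@pytest.fixture(scope="session")
def ref_stats(ref_pairs):
    return lmk.reference_threshold(ref_pairs)


@pytest.fixture(scope="session")
def clean_set():
    """Clean synthetic images (no occluder) with ground-truth landmarks."""
    out = []
    for i in range(12):
        spec = syn.make_spec(seed=3000 + i, laterality="OD" if i % 2 else "OS")
        img, truth = syn.generate_fundus(spec)
        out.append((img, truth, spec))
    return out


@pytest.fixture(scope="session")
def sf7_crop_set():
    """40 aligned SF7 crops (20 DR / 20 healthy, peripheral lesions) + labels.

    Uses ground-truth landmarks so classifier tests are independent of the
    detector; crops extracted at 448x512 (an exact multiple of the 64-px
    classifier input).
    """
    items = syn.generate_labeled_dataset(20, 20, seed=11, lesion_annulus=(1.15, 1.55))
    crops, labels = [], []
    for it in items:
        img, lm, _ = fg.normalize_laterality(it.image, it.landmarks)
        rot, lm2, _ = fg.align_rotation(img, lm)
        crops.append(fg.extract_field_crop(rot, lm2, "SF7", out_size=(448, 512)))
        labels.append(it.label)
    return crops, labels


@pytest.fixture(scope="session")
def patch_unet():
    """U-Net trained on 64-px candidate patches + held-out full-scale images.

    Patch pairs are cut around jittered disc centers with the native-scaled
    candidate diameter, mirroring the deployment path.
    """
    rng = np.random.default_rng(777)
    base = syn.make_spec(seed=999)
    pairs = syn.generate_disc_mask_pairs(16, base, seed=555)
    diameter = max(32, int(round(614 * lmk.native_scale(pairs[0][0].shape))))
    patch_pairs = []
    for img, mask in pairs:
        center, _, _ = lmk.fit_ellipse(mask)
        jitter = rng.uniform(-8, 8, size=2)
        c = (center[0] + jitter[0], center[1] + jitter[1])
        patch_pairs.append((lmk.crop_candidate(img, c, diameter, 64),
                            lmk.crop_candidate_mask(mask, c, diameter, 64)))
    cfg = odu.SegTrainConfig(input_size=64, base_channels=8, depth=3, batch_size=2,
                             seed=1)
    model = odu.train_unet(patch_pairs, cfg)
    held_out = []
    for i in range(10):
        spec = syn.make_spec(seed=8800 + i, laterality="OD" if i % 2 else "OS")
        img, truth = syn.generate_fundus(spec)
        held_out.append((img, truth))
    return model, held_out, diameter
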