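import numpy as np
import pytest

from nucquant import fixtures


@pytest.fixture(scope="session")
def small_patch():
    """One 96-px synthetic patch with 5 well-separated nuclei."""
    cfg = fixtures.SynthPatchConfig(
        patch_size=96, n_nuclei=(5, 5), radius=(4.0, 7.0),
        touching_fraction=0.0, seed=11)
    rgb, labels = fixtures.generate_patch(cfg)
    return rgb, labels


@pytest.fixture(scope="session")
def patch_bank():
    """A bank of 60 small training patches shared by the slow model tests."""
    out = []
    for i in range(60):
        cfg = fixtures.SynthPatchConfig(
            patch_size=64, n_nuclei=(3, 7), radius=(4.0, 7.0),
            touching_fraction=0.2, seed=500 + i)
        out.append(fixtures.generate_patch(cfg))
    return out


def random_instance_maps(rng, shape=(24, 24), n_gt=3, jitter=2):
    """A ground-truth instance map of disjoint rectangles plus a perturbed
    prediction (each instance shifted by up to ``jitter`` px, one in five
    dropped, occasional spurious blob).  Used as a realistic fixture family
    for the metric-oracle comparisons."""
    gt = np.zeros(shape, dtype=np.int32)
    pred = np.zeros(shape, dtype=np.int32)
    placed = 0
    tries = 0
    while placed < n_gt and tries < 200:
        tries += 1
        h, w = rng.integers(3, 7, size=2)
        r0 = rng.integers(0, shape[0] - h - jitter)
        c0 = rng.integers(0, shape[1] - w - jitter)
        region = gt[max(r0 - 1, 0):r0 + h + 1 + jitter,
                    max(c0 - 1, 0):c0 + w + 1 + jitter]
        if (region > 0).any():
            continue
        placed += 1
        gt[r0:r0 + h, c0:c0 + w] = placed
        if rng.random() < 0.8:  # predicted, with jitter
            dr, dc = rng.integers(0, jitter + 1, size=2)
            pred[r0 + dr:r0 + dr + h, c0 + dc:c0 + dc + w] = placed
    if rng.random() < 0.3:  # spurious prediction in a free corner
        free = (gt == 0) & (pred == 0)
        rr, cc = np.nonzero(free)
        if len(rr):
            k = rng.integers(len(rr))
            r0, c0 = rr[k], cc[k]
            blob = pred[r0:r0 + 2, c0:c0 + 2]
            region_gt = gt[r0:r0 + 2, c0:c0 + 2]
            if (blob == 0).all() and (region_gt == 0).all():
                pred[r0:r0 + 2, c0:c0 + 2] = pred.max() + 1
    return gt, pred
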