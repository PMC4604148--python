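import math

import numpy as np
import pytest

from punctacoloc import SceneConfig, make_scene, render_frame


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def scene_at_snr(
    snr: float,
    seed: int,
    n_spots: int = 50,
    sigma: float = 1.5,
    read_noise: float = 10.0,
):
    """Well-separated spots whose peak height is ``snr`` read-noise sigmas.

    Poisson noise is off and gain is 1, so the only noise is the Gaussian
    read noise and the peak SNR is exactly amplitude_peak / read_noise.
    """
    amplitude = snr * read_noise * 2 * math.pi * sigma**2
    cfg = SceneConfig(
        n_spots=n_spots,
        overlap_fraction=1.0,
        amplitude=amplitude,
        amplitude_jitter=0.0,
        background=50.0,
        poisson=False,
        read_noise=read_noise,
        gain=1.0,
        offset=0.0,
        min_separation=8.0,
        seed=seed,
    )
    scene = make_scene(cfg)
    marker = render_frame(scene, 0)[1]
    return scene, marker


def mask_object_metrics(scene, mask: np.ndarray) -> tuple[float, float, float]:
    """Object-level (precision, recall, F1) of a mask against true spot centers.

    A spot counts as recovered if its (rounded) center lies inside a mask
    object; mask objects containing no spot center are false positives.
    """
    from skimage.measure import label as sklabel

    lab = sklabel(mask)
    hits: set[int] = set()
    tp = 0
    for s in scene.spots:
        l = lab[int(round(s.row)), int(round(s.col))]
        if l > 0:
            tp += 1
            hits.add(l)
    fp = int(lab.max()) - len(hits)
    fn = len(scene.spots) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


@pytest.fixture
def snr_scene():
    return scene_at_snr


@pytest.fixture
def object_metrics():
    return mask_object_metrics
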