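"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from tomastem.rgbd import RGBDPair


def brute_otsu(n):
    """Independent exhaustive-scan oracle for the breadth-histogram Otsu.

    Computes class weights/means by direct slicing (no cumulative sums)
    and returns (sigma_b2_curve, k_star) with smallest-k tie-breaking.
    """
    n = np.asarray(n, float)
    L = len(n)
    N = n.sum()
    p = n / N
    pos = np.arange(1, L + 1, dtype=float)
    curve = np.zeros(L)
    for k in range(1, L + 1):
        w0 = p[:k].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (pos[:k] * p[:k]).sum() / w0
        mu1 = (pos[k:] * p[k:]).sum() / w1
        curve[k - 1] = w0 * w1 * (mu1 - mu0) ** 2
    best = float(curve.max())
    k_star = int(np.flatnonzero(curve >= best - 1e-12 * max(best, 1.0))[0]) + 1
    return curve, k_star


def brute_within_class(n, k):
    """Within-class variance sigma_W^2(k) by direct evaluation."""
    n = np.asarray(n, float)
    p = n / n.sum()
    pos = np.arange(1, len(n) + 1, dtype=float)
    w0 = p[:k].sum()
    w1 = 1.0 - w0
    out = 0.0
    if w0 > 0:
        mu0 = (pos[:k] * p[:k]).sum() / w0
        out += ((pos[:k] - mu0) ** 2 * p[:k]).sum()
    if w1 > 0:
        mu1 = (pos[k:] * p[k:]).sum() / w1
        out += ((pos[k:] - mu1) ** 2 * p[k:]).sum()
    return out


def make_pair(depth, color=None):
    depth = np.asarray(depth)
    if color is None:
        color = np.zeros(depth.shape + (3,), np.uint8)
    return RGBDPair(depth=depth, color=color)


@pytest.fixture
def vertical_line_skeleton():
    """A clean 60-px one-pixel vertical line in a 100x50 frame."""
    img = np.zeros((100, 50), bool)
    img[20:80, 25] = True
    return img


@pytest.fixture(scope="session")
def easy_scene():
    """One rendered easy benchmark scene (pair + ground truth)."""
    from tomastem.synthetic import make_scene
    return make_scene("ordinary", "easy", 42)


@pytest.fixture(scope="session")
def grown_stages():
    """Ordinary-variety growth sequence for the worked choice string."""
    from tomastem import lsystem as ls
    rules = ls.load_grammar("ordinary")
    axiom = ls.make_axiom((2, 2, 1, 2, 1, 2, 3, 1, 5))
    return ls.grow(axiom, 14, rules)


@pytest.fixture
def tiny_texture_db(tmp_path):
    """A small on-disk texture DB with three stem and two leaf patches."""
    from tomastem.texture_db import TextureDB, TexturePatch
    db = TextureDB(tmp_path / "db")
    rng = np.random.default_rng(0)
    for _ in range(3):
        img = rng.integers(0, 255, (12, 8, 4), dtype=np.uint8)
        img[:, :, 3] = 255
        db.write(TexturePatch(image=img, organ="stem"))
    for _ in range(2):
        img = rng.integers(0, 255, (16, 16, 4), dtype=np.uint8)
        img[:, :, 3] = 255
        db.write(TexturePatch(image=img, organ="leaf"))
    return db
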