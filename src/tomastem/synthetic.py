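"""Synthetic Kinect-like RGB-D rendering of plant scenes.

Stands in for the depth camera: a pinhole z-buffer projection of a scene
graph produces a registered depth/color pair (depth in millimetres,
0 = no reading) together with ground-truth main-stem polylines in pixel
coordinates.  A noise model reproduces the sparse, fragmented look of
consumer structured-light depth: millimetre quantization, seeded per-pixel
dropout, and erosion of silhouette edges.

The camera defaults emulate the acquisition geometry of the study this
toolkit targets: 640x480, focal length 575 px, potted plant at 950 mm
(within the 0.9-1.0 m working band).  ``make_benchmark`` renders batches
of randomized parametric potted plants -- wide canopy, bare thin waist,
wide pot ("fat-thin-fat") -- so the whole detection pipeline can be
exercised and scored with zero external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import erosion as _erosion
from skimage.morphology import footprint_rectangle

from .errors import ProjectionError
from .geometry import GeomParams, Node, SceneGraph, _rot, _tf, node_mesh
from .metrics import GroundTruth
from .rgbd import RGBDPair


@dataclass
class CameraModel:
    width: int = 640
    height: int = 480
    focal_px: float = 575.0
    cx: float | None = None
    cy: float | None = None
    distance_mm: float = 950.0

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if self.cx is None:
            self.cx = self.width / 2.0
        if self.cy is None:
            self.cy = self.height / 2.0


@dataclass
class NoiseModel:
    dropout_prob: float = 0.0
    quant_mm: int = 2
    edge_erosion_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.quant_mm < 1:
            raise ValueError("quant_mm must be >= 1")


# ---------------------------------------------------------------------------
# scene -> camera-space primitives (mm)

def _scene_primitives(scene: SceneGraph, cam: CameraModel):
    """Cylinders/spheres/polygons in camera coordinates (x right, y down, z out).

    Scene coordinates are cm with +y up; the scene is placed so its bottom
    sits near the lower part of the frame at the camera working distance.
    """
    worlds = scene.world_transforms()
    lo, hi = scene.bbox()
    y_bottom_row = 0.92 * cam.height
    y_off = (y_bottom_row - cam.cy) * cam.distance_mm / cam.focal_px

    def to_cam(p_scene: np.ndarray, z_extra: float = 0.0) -> np.ndarray:
        p = np.asarray(p_scene, float) * 10.0   # cm -> mm
        return np.array([p[0],
                         -(p[1] - lo[1] * 10.0) + y_off,
                         cam.distance_mm + p[2] + z_extra])

    prims = []
    for n, w in zip(scene.nodes, worlds):
        p0 = w[:3, 3]
        if n.kind in ("stem", "stalk"):
            p1 = p0 + w[:3, 0] * n.length
            prims.append(("cyl", to_cam(p0), to_cam(p1), n.radius * 10.0,
                          n.color, n))
        elif n.kind == "pot":
            h, r0, r1 = n.length, n.radius * 0.78, n.radius
            corners = [p0 + w[:3, 1] * r0, p0 - w[:3, 1] * r0,
                       p0 + w[:3, 0] * h - w[:3, 1] * r1,
                       p0 + w[:3, 0] * h + w[:3, 1] * r1]
            prims.append(("poly", [to_cam(c) for c in corners], n.color, n))
        elif n.kind == "leaf":
            s = n.length
            local = np.array([[0, 0, 0], [0.5 * s, 0.35 * s, 0],
                              [s, 0, -0.12 * s], [0.5 * s, -0.35 * s, 0]])
            corners = [(w[:3, :3] @ c) + p0 for c in local]
            prims.append(("poly", [to_cam(c) for c in corners], n.color, n))
        elif n.kind in ("fruit", "flower", "bud"):
            prims.append(("sph", to_cam(p0), max(n.radius, 0.3) * 10.0,
                          n.color, n))
    return prims, worlds, to_cam


def _project(cam: CameraModel, p: np.ndarray) -> tuple[float, float, float]:
    if p[2] <= 0:
        raise ProjectionError("scene point at or behind the camera")
    return (cam.cx + cam.focal_px * p[0] / p[2],
            cam.cy + cam.focal_px * p[1] / p[2], p[2])


def render_rgbd(scene: SceneGraph, cam: CameraModel | None = None,
                noise: NoiseModel | None = None,
                ) -> tuple[RGBDPair, GroundTruth]:
    """Pinhole z-buffer render to a registered depth/color pair + ground truth.

    Depth is millimetres (0 = background / dropout), quantized to
    ``noise.quant_mm``; dropout and edge erosion are seeded.  Ground truth
    lists the projected main-stem polylines (depth-0 stem node chains).
    """
    cam = cam or CameraModel()
    noise = noise or NoiseModel()
    H, W = cam.height, cam.width
    zbuf = np.full((H, W), np.inf)
    color = np.zeros((H, W, 3), np.uint8)
    prims, worlds, to_cam = _scene_primitives(scene, cam)

    def paint(rr, cc, z, col):
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        rr, cc = rr[ok], cc[ok]
        z = z[ok] if np.ndim(z) else np.full(len(rr), z)
        closer = z < zbuf[rr, cc]
        rr, cc, z = rr[closer], cc[closer], z[closer]
        zbuf[rr, cc] = z
        color[rr, cc] = tuple(int(round(255 * c)) for c in col)

    for prim in prims:
        if prim[0] == "cyl":
            _, a, b, r_mm, col, _n = prim
            ca, ra, za = _project(cam, a)
            cb, rb, zb = _project(cam, b)
            half = max(1.0, cam.focal_px * r_mm / ((za + zb) / 2)) / 1.0
            d = np.array([cb - ca, rb - ra])
            L = np.hypot(*d)
            perp = (np.array([-d[1], d[0]]) / L * half) if L > 0 else np.array([half, 0])
            quad_r = np.array([ra + perp[1], rb + perp[1], rb - perp[1], ra - perp[1]])
            quad_c = np.array([ca + perp[0], cb + perp[0], cb - perp[0], ca - perp[0]])
            rr, cc = _draw_polygon(quad_r, quad_c, shape=(H, W))
            if L > 0:
                t = ((cc - ca) * d[0] + (rr - ra) * d[1]) / (L * L)
                t = np.clip(t, 0, 1)
            else:
                t = np.zeros(len(rr))
            paint(rr, cc, za + t * (zb - za) - r_mm, col)
        elif prim[0] == "poly":
            _, corners, col, _n = prim
            proj = [_project(cam, c) for c in corners]
            rr, cc = _draw_polygon([p[1] for p in proj], [p[0] for p in proj],
                                   shape=(H, W))
            paint(rr, cc, float(np.mean([p[2] for p in proj])), col)
        elif prim[0] == "sph":
            _, c3, r_mm, col, _n = prim
            cc0, rr0, z = _project(cam, c3)
            rad = max(1.0, cam.focal_px * r_mm / z)
            rr, cc = _draw_disk((rr0, cc0), rad, shape=(H, W))
            paint(rr, cc, z - r_mm, col)

    depth = np.where(np.isfinite(zbuf), zbuf, 0.0)
    depth = np.round(depth / noise.quant_mm) * noise.quant_mm

    rng = np.random.default_rng(noise.seed)
    if noise.edge_erosion_px > 0:
        fg = depth > 0
        k = 2 * noise.edge_erosion_px + 1
        depth = np.where(_erosion(fg, footprint_rectangle((k, k))), depth, 0.0)
    if noise.dropout_prob > 0:
        drop = rng.random(depth.shape) < noise.dropout_prob
        depth = np.where(drop, 0.0, depth)
    color[depth == 0] = 0

    pair = RGBDPair(depth=depth.astype(np.int64), color=color,
                    meta={"camera": "synthetic", "distance_mm": cam.distance_mm})

    # ground truth: chains of depth-0 main-stem nodes, grouped per stem
    stems: dict[int, list] = {}
    for i, n in enumerate(scene.nodes):
        if n.kind == "stem" and n.depth == 0:
            stems.setdefault(n.branch_id, []).append(i)
    polylines = []
    for _, idxs in sorted(stems.items()):
        pts = []
        for i in idxs:
            w = worlds[i]
            pts.append(w[:3, 3])
        last = scene.nodes[idxs[-1]]
        w = worlds[idxs[-1]]
        pts.append(w[:3, 3] + w[:3, 0] * last.length)
        poly = []
        for p in pts:
            c, r, _ = _project(cam, to_cam(p))
            poly.append([round(float(c), 2), round(float(r), 2)])
        polylines.append(poly)
    return pair, GroundTruth(image_id="synthetic", main_stems=polylines)


# ---------------------------------------------------------------------------
# parametric benchmark plants

def parametric_plant(seed: int, difficulty: str = "easy",
                     variety: str = "ordinary") -> SceneGraph:
    """A randomized potted plant with an explicit fat-thin-fat silhouette.

    Dense canopy of leaf blades at the top, one or two bare main stems
    through the waist, a wide pot at the bottom.  'hard' scenes thin the
    canopy out (partial canopy); the heavy depth dropout of hard benchmarks
    comes from the noise model, not the geometry.
    """
    if difficulty not in ("easy", "hard"):
        raise ValueError("difficulty must be 'easy' or 'hard'")
    rng = np.random.default_rng(seed)
    up = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    nodes = [Node(kind="root", letter="", parent=-1, local=np.eye(4))]
    nodes.append(Node(kind="pot", letter="", parent=0,
                      local=_tf(up, np.zeros(3)),
                      length=12.0, radius=8.5, color=(0.55, 0.30, 0.16)))

    n_stems = 1 + int(rng.random() < 0.5)
    height = float(rng.uniform(*(36, 44) if variety == "cherry" else (42, 52)))
    canopy_frac = 0.40
    n_leaves_total = (int(rng.integers(34, 46)) if difficulty == "easy"
                      else int(rng.integers(12, 20)))

    for s_id in range(n_stems):
        x0 = 0.0 if n_stems == 1 else (-3.5 if s_id == 0 else 3.5)
        tilt = float(rng.uniform(-3.0, 3.0))
        Rm = _rot(np.array([0.0, 0.0, 1.0]), tilt) @ up
        pos = np.array([x0, 10.0, float(rng.uniform(-2, 2))])
        parent = 0
        parent_world = np.eye(4)
        n_seg = 8
        seg = height / n_seg
        for _k in range(n_seg):
            world = _tf(Rm, pos)
            nodes.append(Node(kind="stem", letter="F", parent=parent,
                              local=np.linalg.inv(parent_world) @ world,
                              length=seg, radius=0.5, depth=0, branch_id=s_id,
                              color=(0.42, 0.55, 0.25)))
            parent = len(nodes) - 1
            parent_world = world
            pos = pos + Rm[:, 0] * seg
            Rm = _rot(np.array([0.0, 0.0, 1.0]), float(rng.uniform(-1, 1))) @ Rm
        # canopy leaves on the top part of this stem
        n_leaves = n_leaves_total // n_stems
        top = pos
        for _ in range(n_leaves):
            t = float(rng.uniform(0.0, canopy_frac))
            base = top - Rm[:, 0] * (t * height)
            az = float(rng.uniform(0, 360))
            pitch = float(rng.uniform(50, 85))
            Lr = _rot(np.array([0.0, 1.0, 0.0]), az) @ up
            Lr = _rot(Lr[:, 1], pitch) @ Lr
            size = (float(rng.uniform(8, 14)) if difficulty == "easy"
                    else float(rng.uniform(6, 10)))
            nodes.append(Node(kind="leaf", letter="L", parent=parent,
                              local=np.linalg.inv(parent_world) @ _tf(Lr, base),
                              length=size, depth=1, branch_id=s_id,
                              color=(0.18, 0.50, 0.13)))
    return SceneGraph(nodes)


NOISE_BY_DIFFICULTY = {
    "easy": dict(dropout_prob=0.05, quant_mm=2, edge_erosion_px=1),
    "hard": dict(dropout_prob=0.20, quant_mm=2, edge_erosion_px=1),
}


def make_scene(variety: str, difficulty: str, seed: int,
               cam: CameraModel | None = None):
    """One benchmark scene: rendered pair + ground truth, fully seeded."""
    scene = parametric_plant(seed, difficulty=difficulty, variety=variety)
    noise = NoiseModel(seed=seed, **NOISE_BY_DIFFICULTY[difficulty])
    return render_rgbd(scene, cam or CameraModel(), noise)


def make_benchmark(variety: str, n_scenes: int, difficulty: str, seed: int,
                   out_dir) -> Path:
    """Write a benchmark dataset directory and return its path.

    Layout: depth_%03d.png, color_%03d.png, gt_%03d.json, manifest.json;
    the manifest records every per-scene seed so any scene can be re-rendered.
    """
    from .rgbd import save_color, save_depth

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1,
                                                       size=n_scenes)
    manifest = {"variety": variety, "difficulty": difficulty,
                "seed": int(seed), "scenes": []}
    for i, s in enumerate(scene_seeds):
        pair, gt = make_scene(variety, difficulty, int(s))
        save_depth(out / f"depth_{i:03d}.png", pair.depth)
        save_color(out / f"color_{i:03d}.png", pair.color)
        (out / f"gt_{i:03d}.json").write_text(gt.to_json())
        manifest["scenes"].append({
            "depth": f"depth_{i:03d}.png", "color": f"color_{i:03d}.png",
            "gt": f"gt_{i:03d}.json", "seed": int(s)})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
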