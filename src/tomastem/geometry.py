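"""Turtle interpretation of tomato L-strings into a 3D scene graph.

Symbols map to organ primitives: F/S/f/h extrude tapered stem frustums,
P/Y extrude thin stalks, L/l emit Bezier-surface leaves (a 4x4 control
grid whose mid-rib is lowered to curve the blade -- leaves are never flat
planes), G emits fruit spheres whose color ripens from green to red with
age, H flowers and y buds are small procedural primitives.  Brackets push
and pop the turtle state to form branches.  Rotation operators turn the
orthonormal heading/left/up frame: + and - yaw about up, & and # pitch
about left (branch and leaf insertion), / rolls about the heading (default
137.5 deg, so successive lateral branches spiral around the main stem).

After interpretation the scene can be post-processed: ``apply_bending``
pitches every lateral branch toward gravity, the more the longer the
branch, and adds a small per-internode deflection to the main stem;
``randomize`` draws the four stochastic perturbations (stalk angles,
branch positions, branch lengths, leaf counts) from one seed;
``assign_textures`` samples stem/leaf patches from a texture database.
Scenes export to Wavefront OBJ + MTL (+ copied texture PNGs).

All lengths are centimetres, all angles degrees.
"""

from __future__ import annotations

import colorsys
import copy
import math
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import EmptyDBError, StructureError
from .lsystem import DEFAULT_MATURITY, LString, R

_GRAVITY = np.array([0.0, -1.0, 0.0])

STEM_LETTERS = {"F": "stem", "S": "stem", "f": "stem", "h": "stem",
                "P": "stalk", "Y": "stalk"}
LEAF_LETTERS = {"L": "leaf", "l": "leaf"}


@dataclass
class GeomParams:
    internode_cm: float = 6.0          # main-stem internode length
    branch_segment_cm: float = 4.0     # lateral branch internode length
    stalk_cm: float = 2.0              # flower/bud stalk length
    branch_angle_deg: float = 40.0     # & default
    leaf_angle_deg: float = 30.0       # '#' default
    turn_angle_deg: float = 25.0       # +/- default
    roll_angle_deg: float = 137.5      # / default (phyllotactic spiral)
    initial_radius_cm: float = 0.6
    radius_depth_decay: float = 0.92   # radius factor per branching depth
    taper: float = 0.95                # tip/base radius per internode
    leaf_size_cm: float = 7.0
    fruit_radius_cm: float = 1.4
    flower_size_cm: float = 0.8
    fruit_max_age: int = DEFAULT_MATURITY["G"]
    branch_curvature_deg_per_cm: float = 1.5
    branch_curvature_cap_deg: float = 85.0
    main_stem_deflect_max_deg: float = 3.0
    rand_stalk_angle_deg: float = 10.0
    rand_branch_pos_frac: float = 0.3
    rand_branch_len_frac: float = 0.2
    rand_leaf_count: int = 1
    include_pot: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.branch_angle_deg, self.leaf_angle_deg,
                  self.turn_angle_deg):
            if not 0.0 < a < 180.0:
                raise ValueError("insertion angles must lie in (0, 180) degrees")
        if self.branch_curvature_deg_per_cm < 0:
            raise ValueError("curvature coefficient must be >= 0")


@dataclass
class Node:
    kind: str                      # root/pot/stem/stalk/leaf/fruit/flower/bud
    letter: str
    parent: int
    local: np.ndarray              # 4x4 transform relative to parent
    length: float = 0.0
    radius: float = 0.0
    age: object = 0
    depth: int = 0
    branch_id: int = -1
    cum_len: float = 0.0           # branch length accumulated before this node
    texture: dict | None = None
    color: tuple = (0.42, 0.55, 0.25)


class SceneGraph:
    """Organ primitives with parent-child attachment; node 0 is the root."""

    def __init__(self, nodes: list[Node]):
        self.nodes = nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def world_transforms(self) -> list[np.ndarray]:
        worlds: list[np.ndarray] = []
        for n in self.nodes:
            if n.parent < 0:
                worlds.append(n.local.copy())
            else:
                worlds.append(worlds[n.parent] @ n.local)
        return worlds

    def organ_nodes(self, *kinds: str) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.kind in kinds]

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        pts = []
        for n, w in zip(self.nodes, self.world_transforms()):
            pts.append(w[:3, 3])
            if n.length:
                pts.append(w[:3, 3] + w[:3, 0] * n.length)
            if n.radius:
                pts.append(w[:3, 3] + n.radius)
                pts.append(w[:3, 3] - n.radius)
        pts = np.asarray(pts)
        return pts.min(axis=0), pts.max(axis=0)

    def copy(self) -> "SceneGraph":
        return SceneGraph([replace(n, local=n.local.copy()) for n in self.nodes])


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def _tf(Rm: np.ndarray, p: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = Rm
    m[:3, 3] = p
    return m


def _age_scale(age, maturity: int) -> float:
    """Organ size factor: 0.3 at age 0, 1.0 at maturity or state r."""
    if age == R:
        return 1.0
    return 0.3 + 0.7 * min(int(age), maturity) / maturity


# ---------------------------------------------------------------------------
# randomness: the four perturbation mechanisms

@dataclass
class Perturbation:
    """Seeded jitter tables consumed in string order during interpretation."""

    stalk_angle: np.ndarray = field(default_factory=lambda: np.zeros(0))
    branch_pos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    branch_len: np.ndarray = field(default_factory=lambda: np.ones(0))
    leaf_delta: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


def randomize(s: LString, gp: GeomParams, seed: int) -> Perturbation:
    """Draw the four stochastic perturbations for one rendering.

    (1) the insertion angle of each leaf/flower stalk, (2) the attachment
    position of each lateral branch along the main stem, (3) the length of
    each lateral branch, (4) the number of leaves on a branch (one leaf
    dropped or duplicated).  All draws flow from ``seed``; zero-width
    ranges reproduce the unperturbed scene exactly.
    """
    n_ops = sum(1 for sym in s if sym.letter in "#&")
    depth = 0
    n_branches = 0
    for sym in s:
        if sym.letter == "[":
            depth += 1
            if depth == 1:
                n_branches += 1
        elif sym.letter == "]":
            depth -= 1
    rng = np.random.default_rng(seed)
    a = gp.rand_stalk_angle_deg
    stalk = rng.uniform(-a, a, n_ops) if a > 0 else np.zeros(n_ops)
    p = gp.rand_branch_pos_frac
    pos = rng.uniform(-p, p, n_branches) if p > 0 else np.zeros(n_branches)
    ln = gp.rand_branch_len_frac
    lens = rng.uniform(1 - ln, 1 + ln, n_branches) if ln > 0 else np.ones(n_branches)
    if gp.rand_leaf_count > 0:
        delta = rng.integers(-gp.rand_leaf_count, gp.rand_leaf_count + 1,
                             n_branches)
    else:
        delta = np.zeros(n_branches, int)
    return Perturbation(stalk_angle=stalk, branch_pos=pos,
                        branch_len=lens, leaf_delta=delta)


# ---------------------------------------------------------------------------

def interpret(s: LString, gp: GeomParams | None = None,
              perturb: Perturbation | None = None) -> SceneGraph:
    """Build the scene graph for one L-string.

    Total on bracket-balanced strings; node count is linear in the number
    of organ symbols.
    """
    gp = gp or GeomParams()
    pe = perturb or Perturbation()

    # frame columns = (heading, left, up); the turtle starts pointing up
    _UP = np.array([[0.0, 1.0, 0.0],
                    [1.0, 0.0, 0.0],
                    [0.0, 0.0, 1.0]])
    nodes = [Node(kind="root", letter="", parent=-1, local=np.eye(4))]
    if gp.include_pot:
        nodes.append(Node(kind="pot", letter="", parent=0,
                          local=_tf(_UP, np.zeros(3)),
                          length=12.0, radius=9.0, color=(0.55, 0.30, 0.16)))
    Rm = _UP.copy()
    pos = np.zeros(3)
    parent, radius, depth, branch, cum = 0, gp.initial_radius_cm, 0, -1, 0.0
    stack: list[tuple] = []
    op_i = br_i = 0
    n_leaves_emitted = 0

    def jitter() -> float:
        nonlocal op_i
        j = float(pe.stalk_angle[op_i]) if op_i < len(pe.stalk_angle) else 0.0
        op_i += 1
        return j

    def emit(kind, letter, length, rad, age, color=None) -> None:
        nonlocal parent
        local = np.linalg.inv(worlds[parent]) @ _tf(Rm, pos)
        n = Node(kind=kind, letter=letter, parent=parent, local=local,
                 length=length, radius=rad, age=age, depth=depth,
                 branch_id=branch, cum_len=cum)
        if color is not None:
            n.color = color
        nodes.append(n)
        worlds.append(_tf(Rm, pos))

    worlds = [np.eye(4)] + [np.eye(4)] * (len(nodes) - 1)

    for sym in s:
        c = sym.letter
        if c == "[":
            if depth == 0:
                branch = br_i
                if br_i < len(pe.branch_pos):      # mechanism 2
                    pos = pos + Rm[:, 0] * (pe.branch_pos[br_i] * gp.internode_cm)
                br_i += 1
                n_leaves_emitted = 0
            stack.append((Rm.copy(), pos.copy(), parent, radius, depth,
                          branch, cum))
            depth += 1
            radius *= gp.radius_depth_decay
        elif c == "]":
            if not stack:
                raise StructureError("unbalanced ']' during interpretation")
            Rm, pos, parent, radius, depth, branch, cum = stack.pop()
        elif c == "+":
            ang = sym.params[0] if sym.params else gp.turn_angle_deg
            Rm = _rot(Rm[:, 2], float(ang)) @ Rm
        elif c == "-":
            ang = sym.params[0] if sym.params else gp.turn_angle_deg
            Rm = _rot(Rm[:, 2], -float(ang)) @ Rm
        elif c == "&":
            ang = (sym.params[0] if sym.params else gp.branch_angle_deg) + jitter()
            Rm = _rot(Rm[:, 1], float(ang)) @ Rm
        elif c == "#":
            ang = (sym.params[0] if sym.params else gp.leaf_angle_deg) + jitter()
            Rm = _rot(Rm[:, 1], float(ang)) @ Rm
        elif c == "/":
            ang = sym.params[0] if sym.params else gp.roll_angle_deg
            Rm = _rot(Rm[:, 0], float(ang)) @ Rm
        elif c in STEM_LETTERS:
            age = sym.params[-1] if sym.params else R
            base = gp.internode_cm if c == "F" else (
                gp.stalk_cm if c in "PY" else gp.branch_segment_cm)
            scale = _age_scale(age, DEFAULT_MATURITY.get(c, 5))
            if depth > 0 and 0 <= branch < len(pe.branch_len):  # mechanism 3
                scale *= float(pe.branch_len[branch])
            length = base * scale
            emit(STEM_LETTERS[c], c, length, radius, age,
                 color=(0.42, 0.55, 0.25))
            parent = len(nodes) - 1
            pos = pos + Rm[:, 0] * length
            cum += length
            radius *= gp.taper
        elif c in LEAF_LETTERS:
            age = sym.params[-1] if sym.params else R
            delta = (int(pe.leaf_delta[branch])
                     if 0 <= branch < len(pe.leaf_delta) else 0)
            if delta < 0 and n_leaves_emitted == 0:       # mechanism 4: drop one
                n_leaves_emitted += 1
                continue
            emit("leaf", c, gp.leaf_size_cm * _age_scale(age, DEFAULT_MATURITY[c]),
                 0.0, age, color=(0.18, 0.50, 0.13))
            if delta > 0 and n_leaves_emitted == 0:       # mechanism 4: add one
                Rm2 = Rm
                Rm = _rot(Rm[:, 2], gp.turn_angle_deg) @ Rm
                emit("leaf", c, gp.leaf_size_cm * _age_scale(age, DEFAULT_MATURITY[c]),
                     0.0, age, color=(0.18, 0.50, 0.13))
                Rm = Rm2
            n_leaves_emitted += 1
        elif c == "G":
            age = sym.params[-1] if sym.params else R
            emit("fruit", c, 0.0,
                 gp.fruit_radius_cm * _age_scale(age, gp.fruit_max_age),
                 age, color=ripen_color(age if age != R else gp.fruit_max_age,
                                        gp.fruit_max_age))
        elif c == "H":
            age = sym.params[-1] if sym.params else R
            emit("flower", c, 0.0, gp.flower_size_cm, age,
                 color=(0.95, 0.85, 0.15))
        elif c == "y":
            age = sym.params[-1] if sym.params else R
            emit("bud", c, 0.0, 0.4, age, color=(0.35, 0.60, 0.20))
        # control characters A/B/C/D have no geometric entity
    if stack:
        raise StructureError("unbalanced '[' during interpretation")
    return SceneGraph(nodes)


# ---------------------------------------------------------------------------

def apply_bending(scene: SceneGraph, gp: GeomParams) -> SceneGraph:
    """Bend lateral branches toward gravity and wobble the main stem.

    A branch node whose branch has accumulated length l at the node's tip
    is deflected so the cumulative pitch equals
    min(curvature_coefficient * l, cap); longer branches therefore droop
    strictly more, never past the cap.  Each main-stem internode receives a
    small random deflection (uniform in [0, main_stem_deflect_max_deg],
    seeded by ``gp.seed``).  A zero coefficient with zero main-stem
    deflection returns an identical scene.
    """
    out = scene.copy()
    rng = np.random.default_rng(gp.seed)
    coeff = gp.branch_curvature_deg_per_cm
    cap = gp.branch_curvature_cap_deg
    worlds: list[np.ndarray] = []
    for i, n in enumerate(out.nodes):
        pw = np.eye(4) if n.parent < 0 else worlds[n.parent]
        w = pw @ n.local
        ang = 0.0
        if n.kind == "stem" and n.depth >= 1 and coeff > 0:
            ang = (min(coeff * (n.cum_len + n.length), cap)
                   - min(coeff * n.cum_len, cap))
        elif (n.kind == "stem" and n.depth == 0
              and gp.main_stem_deflect_max_deg > 0):
            ang = float(rng.uniform(0.0, gp.main_stem_deflect_max_deg))
        if ang > 1e-12:
            h = w[:3, 0]
            axis = np.cross(h, _GRAVITY)
            if np.linalg.norm(axis) > 1e-9:
                Rw = np.eye(4)
                Rw[:3, :3] = _rot(axis, ang)
                p = w[:3, 3]
                T, Ti = np.eye(4), np.eye(4)
                T[:3, 3], Ti[:3, 3] = p, -p
                w = T @ Rw @ Ti @ w
                n.local = np.linalg.inv(pw) @ w
        worlds.append(w)
    return out


def ripen_color(age: int, max_age: int) -> tuple[float, float, float]:
    """Fruit color, linearly interpolated on the HSV hue circle.

    Age 0 is pure green (hue 120), ``max_age`` pure red (hue 0); ages past
    the maximum clamp to red.
    """
    if max_age <= 0:
        raise ValueError("max_age must be positive")
    t = min(max(int(age), 0), max_age) / max_age
    hue = 120.0 * (1.0 - t)
    return colorsys.hsv_to_rgb(hue / 360.0, 0.85, 0.85)


def assign_textures(scene: SceneGraph, db, seed: int = 0) -> SceneGraph:
    """Sample one stem patch per stem/stalk node and one leaf patch per leaf."""
    out = scene.copy()
    rng = np.random.default_rng(seed)
    root = str(db.root)
    for n in out.nodes:
        if n.kind in ("stem", "stalk"):
            n.texture = dict(db.sample_record("stem", rng), _root=root)
        elif n.kind == "leaf":
            recs = db.records(organ="leaf") + db.records(organ="compound_leaf")
            if not recs:
                raise EmptyDBError("no leaf patches in the database")
            n.texture = dict(recs[int(rng.integers(len(recs)))], _root=root)
    return out


# ---------------------------------------------------------------------------
# meshes and OBJ export

def _frustum(length: float, r0: float, r1: float, sides: int = 12):
    a = np.linspace(0, 2 * np.pi, sides, endpoint=False)
    ring = np.stack([np.zeros(sides), np.cos(a), np.sin(a)], axis=1)
    V = np.vstack([ring * [0, r0, r0],
                   ring * [0, r1, r1] + [length, 0, 0]])
    F = []
    for i in range(sides):
        j = (i + 1) % sides
        F += [[i, j, sides + i], [j, sides + j, sides + i]]
    return V, np.asarray(F)


def _bernstein(n: int, i: int, t: np.ndarray) -> np.ndarray:
    return math.comb(n, i) * t ** i * (1 - t) ** (n - i)


def _leaf_mesh(size: float, samples: int = 8):
    """Bezier-surface blade: 4x4 control grid, mid-rib lowered to curve it."""
    half = np.array([0.04, 0.30, 0.22, 0.0]) * size         # half-width profile
    lat = np.array([-1.0, -1 / 3, 1 / 3, 1.0])
    ctrl = np.zeros((4, 4, 3))
    for i in range(4):
        for j in range(4):
            ctrl[i, j, 0] = (i / 3.0) * size
            ctrl[i, j, 1] = lat[j] * half[i]
            # drop the rib and curl the blade downward toward the tip
            ctrl[i, j, 2] = (-0.12 * size * (i / 3.0) ** 2
                             - 0.06 * size * (1 - abs(lat[j])))
    t = np.linspace(0, 1, samples)
    Bu = np.stack([_bernstein(3, i, t) for i in range(4)], axis=1)  # (s,4)
    P = np.einsum("si,tj,ijk->stk", Bu, Bu, ctrl)
    V = P.reshape(-1, 3)
    F = []
    for i in range(samples - 1):
        for j in range(samples - 1):
            a = i * samples + j
            F += [[a, a + 1, a + samples], [a + 1, a + samples + 1, a + samples]]
    return V, np.asarray(F)


def _uv_sphere(r: float, stacks: int = 8, sectors: int = 10):
    vs = [np.array([0, 0, r])]
    for i in range(1, stacks):
        phi = np.pi * i / stacks
        for j in range(sectors):
            th = 2 * np.pi * j / sectors
            vs.append(r * np.array([np.sin(phi) * np.cos(th),
                                    np.sin(phi) * np.sin(th), np.cos(phi)]))
    vs.append(np.array([0, 0, -r]))
    V = np.asarray(vs)
    F = []
    for j in range(sectors):
        F.append([0, 1 + j, 1 + (j + 1) % sectors])
    for i in range(stacks - 2):
        a = 1 + i * sectors
        b = a + sectors
        for j in range(sectors):
            j2 = (j + 1) % sectors
            F += [[a + j, b + j, a + j2], [a + j2, b + j, b + j2]]
    last = len(V) - 1
    a = 1 + (stacks - 2) * sectors
    for j in range(sectors):
        F.append([last, a + (j + 1) % sectors, a + j])
    return V, np.asarray(F)


def _disc(r: float, sides: int = 8):
    a = np.linspace(0, 2 * np.pi, sides, endpoint=False)
    V = np.vstack([[0, 0, 0], np.stack([np.zeros(sides), r * np.cos(a),
                                        r * np.sin(a)], axis=1)])
    F = [[0, 1 + i, 1 + (i + 1) % sides] for i in range(sides)]
    return V, np.asarray(F)


def node_mesh(n: Node, gp: GeomParams):
    if n.kind in ("stem", "stalk"):
        return _frustum(n.length, n.radius, n.radius * gp.taper)
    if n.kind == "leaf":
        return _leaf_mesh(n.length)
    if n.kind in ("fruit", "bud"):
        return _uv_sphere(n.radius)
    if n.kind == "flower":
        return _disc(n.radius)
    if n.kind == "pot":
        V, F = _frustum(n.length, n.radius * 0.78, n.radius, sides=16)
        return V, F
    return None


def export_obj(scene: SceneGraph, path, gp: GeomParams | None = None) -> list[Path]:
    """Write an OBJ + MTL bundle (textures copied alongside); returns paths.

    Output is byte-deterministic for a given scene: fixed float formatting,
    fixed node order, sorted materials.
    """
    gp = gp or GeomParams()
    path = Path(path)
    obj_path = path.with_suffix(".obj")
    mtl_path = path.with_suffix(".mtl")
    obj_path.parent.mkdir(parents=True, exist_ok=True)

    worlds = scene.world_transforms()
    materials: dict[str, dict] = {}
    out = [f"mtllib {mtl_path.name}"]
    v_off = 1
    written: list[Path] = [obj_path, mtl_path]
    for i, n in enumerate(scene.nodes):
        mesh = node_mesh(n, gp)
        if mesh is None:
            continue
        V, F = mesh
        W = worlds[i]
        Vw = (W[:3, :3] @ V.T).T + W[:3, 3]
        if n.texture is not None:
            mat = "tex_" + Path(n.texture["file"]).stem
            materials[mat] = {"map": n.texture}
        else:
            mat = "col_%02x%02x%02x" % tuple(int(round(255 * c)) for c in n.color)
            materials[mat] = {"kd": n.color}
        out.append(f"o node{i:04d}_{n.kind}")
        out.append(f"usemtl {mat}")
        for v in Vw:
            out.append("v %.6f %.6f %.6f" % tuple(v))
        for f in F:
            out.append("f %d %d %d" % tuple(int(x) + v_off for x in f))
        v_off += len(Vw)
    obj_path.write_text("\n".join(out) + "\n")

    mtl_lines = []
    for name in sorted(materials):
        spec = materials[name]
        mtl_lines.append(f"newmtl {name}")
        if "kd" in spec:
            mtl_lines.append("Kd %.4f %.4f %.4f" % spec["kd"])
        else:
            rec = spec["map"]
            tex_name = Path(rec["file"]).name
            src = Path(rec.get("_root", ".")) / rec["file"]
            dst = obj_path.parent / tex_name
            if src.exists() and src.resolve() != dst.resolve():
                shutil.copyfile(src, dst)
                written.append(dst)
            mtl_lines.append("Kd 1.0000 1.0000 1.0000")
            mtl_lines.append(f"map_Kd {tex_name}")
        mtl_lines.append("")
    mtl_path.write_text("\n".join(mtl_lines))
    return written
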