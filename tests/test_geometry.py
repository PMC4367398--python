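import numpy as np
import pytest

from tomastem import geometry as ge
from tomastem import lsystem as ls
from tomastem.errors import EmptyDBError


def interp(text, **gp_kw):
    gp_kw.setdefault("include_pot", False)
    gp = ge.GeomParams(**gp_kw)
    return ge.interpret(ls.parse_lstring(text), gp), gp


class TestInterpret:
    def test_single_internode(self):
        scene, gp = interp("F(r)")
        stems = scene.organ_nodes("stem")
        assert len(stems) == 1
        n = scene.nodes[stems[0]]
        w = scene.world_transforms()[stems[0]]
        assert n.length == pytest.approx(gp.internode_cm)
        assert n.radius == pytest.approx(gp.initial_radius_cm)
        np.testing.assert_allclose(w[:3, 3], 0, atol=1e-12)
        np.testing.assert_allclose(w[:3, 0], [0, 1, 0], atol=1e-12)  # up

    def test_symmetric_branches(self):
        """[+F][-F] produce headings mirrored about the parent heading."""
        scene, _ = interp("[+F(r)][-F(r)]")
        a, b = [scene.world_transforms()[i] for i in scene.organ_nodes("stem")]
        ha, hb = a[:3, 0], b[:3, 0]
        assert ha[1] == pytest.approx(hb[1])          # same vertical part
        np.testing.assert_allclose(ha[0], -hb[0], atol=1e-12)

    def test_bracket_changes_attachment_not_geometry(self):
        flat, _ = interp("F(r)F(r)")
        nested, _ = interp("F(r)[F(r)]")
        wf = [w[:3, 3] for w in flat.world_transforms()]
        wn = [w[:3, 3] for w in nested.world_transforms()]
        np.testing.assert_allclose(wf, wn, atol=1e-12)
        depths = [nested.nodes[i].depth for i in nested.organ_nodes("stem")]
        assert depths == [0, 1]

    def test_node_count_linear_in_organ_symbols(self, grown_stages):
        gp = ge.GeomParams(include_pot=False)
        s = grown_stages[10]
        scene = ge.interpret(s, gp)
        organs = sum(1 for sym in s if sym.letter in "LlFSGPHYyhf")
        assert len(scene) == organs + 1          # + root

    def test_unbalanced_rejected(self):
        from tomastem.errors import StructureError
        s = ls.LString.__new__(ls.LString)   # bypass construction validation
        s.symbols = [ls.SymbolInstance("["), ls.SymbolInstance("F", (1,))]
        s.choice = None
        with pytest.raises(StructureError):
            ge.interpret(s, ge.GeomParams())

    def test_growth_height_monotone(self, grown_stages):
        gp = ge.GeomParams(include_pot=False)
        heights = []
        for s in grown_stages:
            lo, hi = ge.interpret(s, gp).bbox()
            heights.append(hi[1] - lo[1])
        assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))


class TestBending:
    def _branch_scene(self, lengths):
        text = "F(r)" + "".join(f"[&{'S(r)' * n}]" for n in lengths)
        return interp(text, main_stem_deflect_max_deg=0.0)

    def _tip_drop(self, scene, gp):
        bent = ge.apply_bending(scene, gp)
        drops = []
        for sc in (scene, bent):
            worlds = sc.world_transforms()
            tips = {}
            for i in sc.organ_nodes("stem"):
                n = sc.nodes[i]
                if n.depth >= 1:
                    tips[n.branch_id] = worlds[i][:3, 3] + worlds[i][:3, 0] * n.length
            drops.append(tips)
        return {k: drops[0][k][1] - drops[1][k][1] for k in drops[0]}

    def test_longer_branch_droops_more(self):
        scene, gp = self._branch_scene([2, 6])
        drop = self._tip_drop(scene, gp)
        assert drop[1] > drop[0] > 0

    def test_zero_coefficient_identity(self):
        scene, gp = interp("F(r)[&S(r)S(r)]",
                           branch_curvature_deg_per_cm=0.0,
                           main_stem_deflect_max_deg=0.0)
        bent = ge.apply_bending(scene, gp)
        for a, b in zip(scene.world_transforms(), bent.world_transforms()):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_deflection_capped(self):
        """Even an absurdly long branch never pitches past the cap: its
        tip cannot drop below the attachment by more than the branch
        length (85 deg < straight down)."""
        scene, gp = self._branch_scene([30])
        gp.branch_curvature_deg_per_cm = 50.0
        bent = ge.apply_bending(scene, gp)
        worlds = bent.world_transforms()
        for i in bent.organ_nodes("stem"):
            n = bent.nodes[i]
            if n.depth >= 1:
                h = worlds[i][:3, 0]
                angle_from_down = np.degrees(np.arccos(np.clip(-h[1], -1, 1)))
                assert angle_from_down > 4.9   # never fully vertical (90-85)


class TestRipenColor:
    def test_endpoints(self):
        g = ge.ripen_color(0, 6)
        r = ge.ripen_color(6, 6)
        assert g[1] > g[0] and g[2] < 0.2        # green anchor
        assert r[0] > r[1] and r[2] < 0.2        # red anchor

    def test_hue_strictly_decreasing(self):
        import colorsys
        hues = [colorsys.rgb_to_hsv(*ge.ripen_color(a, 6))[0] for a in range(7)]
        assert all(a > b for a, b in zip(hues, hues[1:]))

    def test_overripe_clamps(self):
        assert ge.ripen_color(99, 6) == ge.ripen_color(6, 6)


class TestRandomize:
    def _stage(self, grown_stages):
        return grown_stages[10]

    def test_seed_determinism(self, grown_stages):
        gp = ge.GeomParams()
        s = self._stage(grown_stages)
        a = ge.randomize(s, gp, 9)
        b = ge.randomize(s, gp, 9)
        for f in ("stalk_angle", "branch_pos", "branch_len", "leaf_delta"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_zero_ranges_identity(self, grown_stages, tmp_path):
        gp = ge.GeomParams(rand_stalk_angle_deg=0, rand_branch_pos_frac=0,
                           rand_branch_len_frac=0, rand_leaf_count=0,
                           include_pot=False)
        s = self._stage(grown_stages)
        pe = ge.randomize(s, gp, 9)
        a = ge.export_obj(ge.interpret(s, gp, pe), tmp_path / "x", gp)[0]
        b = ge.export_obj(ge.interpret(s, gp), tmp_path / "y", gp)[0]
        assert a.read_text().splitlines()[1:] == b.read_text().splitlines()[1:]

    def test_different_seeds_differ(self, grown_stages):
        """Over many seed pairs, continuous branch-length draws collide
        with probability zero."""
        gp = ge.GeomParams()
        s = self._stage(grown_stages)
        for seed in range(100):
            a = ge.randomize(s, gp, 2 * seed)
            b = ge.randomize(s, gp, 2 * seed + 1)
            assert not np.array_equal(a.branch_len, b.branch_len)


class TestTexturesAndExport:
    def test_assignment_reproducible(self, grown_stages, tiny_texture_db):
        gp = ge.GeomParams()
        scene = ge.interpret(grown_stages[8], gp)
        a = ge.assign_textures(scene, tiny_texture_db, seed=1)
        b = ge.assign_textures(scene, tiny_texture_db, seed=1)
        files_a = [n.texture["file"] for n in a.nodes if n.texture]
        files_b = [n.texture["file"] for n in b.nodes if n.texture]
        assert files_a == files_b and files_a
        stem_files = {n.texture["file"] for n in a.nodes
                      if n.texture and n.kind in ("stem", "stalk")}
        assert stem_files <= {r["file"] for r in tiny_texture_db.records("stem")}

    def test_missing_leaf_category_rejected(self, grown_stages, tmp_path):
        from tomastem.texture_db import TextureDB, TexturePatch
        db = TextureDB(tmp_path / "stems_only")
        img = np.zeros((4, 4, 4), np.uint8)
        img[:, :, 3] = 255
        db.write(TexturePatch(image=img, organ="stem"))
        scene = ge.interpret(grown_stages[8], ge.GeomParams())
        with pytest.raises(EmptyDBError):
            ge.assign_textures(scene, db, seed=0)

    def test_obj_reimport_roundtrip(self, grown_stages, tmp_path):
        import trimesh
        gp = ge.GeomParams()
        scene = ge.apply_bending(ge.interpret(grown_stages[10], gp), gp)
        obj = ge.export_obj(scene, tmp_path / "plant", gp)[0]
        n_v = sum(1 for l in obj.read_text().splitlines() if l.startswith("v "))
        n_f = sum(1 for l in obj.read_text().splitlines() if l.startswith("f "))
        mesh = trimesh.load(obj, process=False, force="mesh")
        assert len(mesh.vertices) == n_v
        assert len(mesh.faces) == n_f

    def test_seeded_export_byte_identical(self, grown_stages, tmp_path):
        gp = ge.GeomParams(seed=4)
        s = grown_stages[9]
        paths = []
        for name in ("a", "b"):
            pe = ge.randomize(s, gp, 4)
            scene = ge.apply_bending(ge.interpret(s, gp, pe), gp)
            paths.append(ge.export_obj(scene, tmp_path / name, gp)[0])
        assert (paths[0].read_text().splitlines()[1:]
                == paths[1].read_text().splitlines()[1:])
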