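"""Organ texture extraction and the growth-phase-indexed texture database.

Stem patches are cropped from the color frame around each validated
segment; leaf cutouts come from photographs of single leaves on a uniform
background via excess-green thresholding (ExG = 2G - R - B) followed by a
largest-connected-component rule.  Patches are stored as RGBA PNGs (alpha
is the foreground support) under ``root/<variety>/<organ>/<phase>/NNN.png``
with a JSON index, and are sampled uniformly (seeded) at render time.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.measure import label

from .errors import EmptyDBError, EmptyPatchError, NoLeafError
from .hough import Segment

ORGANS = ("stem", "leaf", "compound_leaf")
VARIETIES = ("cherry", "ordinary")
DEFAULT_MARGIN_PX = 6
DEFAULT_EXG_TAU = 20


@dataclass
class TexturePatch:
    image: np.ndarray           # (h, w, 4) uint8, alpha = foreground
    organ: str
    variety: str = "ordinary"
    growth_phase: str = "unknown"
    source_segment_id: int | None = None

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}")
        if self.variety not in VARIETIES:
            raise ValueError(f"variety must be one of {VARIETIES}")
        if self.image[:, :, 3].max() == 0:
            raise EmptyPatchError("patch has empty alpha support")


def extract_stem_patch(color: np.ndarray, seg: Segment,
                       margin_px: int = DEFAULT_MARGIN_PX,
                       mask: np.ndarray | None = None,
                       **patch_kw) -> TexturePatch:
    """Axis-aligned crop of a segment's bounding box dilated by a margin.

    Alpha comes from the foreground mask restricted to the crop (all-ones
    when no mask is given).  The crop is clamped to the image; a crop whose
    alpha support is empty raises ``EmptyPatchError``.
    """
    h, w = color.shape[:2]
    c0, c1 = sorted((seg.p0[0], seg.p1[0]))
    r0, r1 = sorted((seg.p0[1], seg.p1[1]))
    if not (0 <= c0 and c1 < w and 0 <= r0 and r1 < h):
        raise ValueError("segment endpoints outside the image")
    r0, r1 = max(0, r0 - margin_px), min(h - 1, r1 + margin_px)
    c0, c1 = max(0, c0 - margin_px), min(w - 1, c1 + margin_px)
    crop = color[r0:r1 + 1, c0:c1 + 1]
    if mask is not None:
        alpha = (np.asarray(mask, bool)[r0:r1 + 1, c0:c1 + 1] * 255).astype(np.uint8)
    else:
        alpha = np.full(crop.shape[:2], 255, np.uint8)
    rgba = np.dstack([crop.astype(np.uint8), alpha])
    patch_kw.setdefault("organ", "stem")
    patch_kw.setdefault("source_segment_id", seg.id)
    return TexturePatch(image=rgba, **patch_kw)


def segment_leaf(color: np.ndarray, tau: int = DEFAULT_EXG_TAU,
                 **patch_kw) -> TexturePatch:
    """Cut a leaf out of a uniform background by excess-green thresholding.

    Pixels with 2G - R - B > tau are candidate leaf pixels; the largest
    connected component becomes the alpha support.
    """
    c = color.astype(np.int64)
    exg = 2 * c[:, :, 1] - c[:, :, 0] - c[:, :, 2]
    fg = exg > tau
    if not fg.any():
        raise NoLeafError(f"no pixel exceeds the excess-green threshold {tau}")
    lab = label(fg, connectivity=2)
    largest = np.argmax(np.bincount(lab[fg].ravel()))
    support = lab == largest
    rows, cols = np.nonzero(support)
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    crop = color[r0:r1 + 1, c0:c1 + 1].astype(np.uint8)
    alpha = (support[r0:r1 + 1, c0:c1 + 1] * 255).astype(np.uint8)
    patch_kw.setdefault("organ", "leaf")
    return TexturePatch(image=np.dstack([crop, alpha]), **patch_kw)


@dataclass
class TextureDB:
    """On-disk patch store: root/<variety>/<organ>/<phase>/NNN.png + index.json."""

    root: Path
    index: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.root.mkdir(parents=True, exist_ok=True)
        idx = self.root / "index.json"
        if idx.exists() and not self.index:
            self.index = json.loads(idx.read_text())

    def _save_index(self) -> None:
        tmp = self.root / "index.json.tmp"
        tmp.write_text(json.dumps(self.index, indent=1))
        os.replace(tmp, self.root / "index.json")

    def write(self, patch: TexturePatch) -> dict:
        """Atomically store a patch and register it in the index."""
        sub = self.root / patch.variety / patch.organ / patch.growth_phase
        sub.mkdir(parents=True, exist_ok=True)
        fname = f"{len(self.index):03d}.png"
        tmp = sub / (fname + ".tmp")
        iio.imwrite(tmp, patch.image, extension=".png")
        os.replace(tmp, sub / fname)
        rec = {
            "file": str((sub / fname).relative_to(self.root)),
            "organ": patch.organ,
            "variety": patch.variety,
            "phase": patch.growth_phase,
            "source_segment_id": patch.source_segment_id,
        }
        self.index.append(rec)
        self._save_index()
        return rec

    def records(self, organ: str | None = None,
                variety: str | None = None) -> list[dict]:
        return [r for r in self.index
                if (organ is None or r["organ"] == organ)
                and (variety is None or r["variety"] == variety)]

    def load(self, rec: dict) -> TexturePatch:
        img = np.asarray(iio.imread(self.root / rec["file"]))
        return TexturePatch(image=img, organ=rec["organ"], variety=rec["variety"],
                            growth_phase=rec["phase"],
                            source_segment_id=rec["source_segment_id"])

    def sample(self, organ: str, variety: str | None = None,
               seed: int = 0) -> TexturePatch:
        """Uniform seeded draw from one category."""
        recs = self.records(organ=organ, variety=variety)
        if not recs:
            raise EmptyDBError(f"no patches for organ={organ}, variety={variety}")
        rng = np.random.default_rng(seed)
        return self.load(recs[int(rng.integers(len(recs)))])

    def sample_record(self, organ: str, rng: np.random.Generator,
                      variety: str | None = None) -> dict:
        recs = self.records(organ=organ, variety=variety)
        if not recs:
            raise EmptyDBError(f"no patches for organ={organ}, variety={variety}")
        return recs[int(rng.integers(len(recs)))]


def db_write(db: TextureDB, patch: TexturePatch) -> dict:
    return db.write(patch)


def db_sample(db: TextureDB, organ: str, variety: str | None = None,
              seed: int = 0) -> TexturePatch:
    return db.sample(organ, variety=variety, seed=seed)
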