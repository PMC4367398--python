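"""Candidate stem detection with the Progressive Probabilistic Hough Transform.

Stems thin to short, roughly straight runs of skeleton pixels, so a
randomized line-segment detector over the binary skeleton recovers them --
together with plenty of false positives inside the canopy and the pot,
which a later geometric stage removes.  The PPHT samples skeleton points
randomly; the random stream is owned by ``PPHTParams.seed`` so the same
seed and input always give a byte-identical segment list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import probabilistic_hough_line


@dataclass(frozen=True)
class Segment:
    """A detected line segment, endpoints as (col, row) pixel coordinates.

    Canonical ordering: p0.row <= p1.row, ties broken by column.
    """

    p0: tuple[int, int]
    p1: tuple[int, int]
    length_px: float
    id: int

    @staticmethod
    def from_endpoints(a, b, id: int = 0) -> "Segment":
        a, b = (tuple(int(v) for v in a), tuple(int(v) for v in b))
        if (a[1], a[0]) > (b[1], b[0]):
            a, b = b, a
        return Segment(p0=a, p1=b, length_px=math.dist(a, b), id=id)

    @property
    def row_span(self) -> tuple[int, int]:
        return self.p0[1], self.p1[1]


@dataclass
class PPHTParams:
    rho_px: float = 1.0
    theta_deg: float = 1.0
    votes: int = 20
    min_len_px: int = 20
    max_gap_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rho_px, self.theta_deg, self.votes,
               self.min_len_px, self.max_gap_px) <= 0:
            raise ValueError("all PPHT parameters must be positive")
        if abs(180.0 / self.theta_deg - round(180.0 / self.theta_deg)) > 1e-9:
            raise ValueError("theta_deg must divide 180 evenly")


def detect_segments(skel, params: PPHTParams | None = None) -> list[Segment]:
    """Run the PPHT on a binary skeleton and return canonical segments.

    The list is sorted by (p0.row, p0.col, p1.row, p1.col) and ids are
    assigned in that order, so a fixed seed reproduces the list exactly.
    """
    params = params or PPHTParams()
    img = np.asarray(getattr(skel, "skel", skel), bool)
    if not img.any():
        return []
    n_theta = int(round(180.0 / params.theta_deg))
    theta = np.linspace(-np.pi / 2, np.pi / 2, n_theta, endpoint=False)
    lines = probabilistic_hough_line(
        img,
        threshold=params.votes,
        line_length=params.min_len_px,
        line_gap=params.max_gap_px,
        theta=theta,
        rng=np.random.default_rng(params.seed),
    )
    segs = [Segment.from_endpoints(a, b) for a, b in lines]
    segs.sort(key=lambda s: (s.p0[1], s.p0[0], s.p1[1], s.p1[0]))
    return [Segment(p0=s.p0, p1=s.p1, length_px=s.length_px, id=i)
            for i, s in enumerate(segs)]


def segments_to_json(segs: list[Segment]) -> str:
    return json.dumps(
        [{"id": s.id, "p0": list(s.p0), "p1": list(s.p1),
          "length_px": round(s.length_px, 4)} for s in segs],
        indent=1)


def segments_from_json(text: str) -> list[Segment]:
    return [Segment.from_endpoints(d["p0"], d["p1"], id=d["id"])
            for d in json.loads(text)]
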