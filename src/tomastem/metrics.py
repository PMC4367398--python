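"""Segment-level evaluation of stem detection.

Counting is done per image against manually annotated main stems, inside
the bounded valley region:

* a detected segment lying on some main stem is a Successful Detection
  (SD); one that is not is a False Positive (FP);
* a main stem covered by at least one detected segment is a True Positive
  (TP); an uncovered main stem is a False Negative (FN).

Batch rates aggregate raw counts over all test images:
FNR = sum(FN)/sum(stems), TPR = sum(TP)/sum(stems), ER = sum(FP)/sum(detected),
Ac = sum(SD)/sum(detected); by construction TPR + FNR = 1 and Ac + ER = 1.

"Lying on" a stem is not a metric notion in itself; here a segment matches
a stem polyline when the mean point-to-polyline distance over the segment
is at most ``match_dist_px`` (default 5 px, about one stem width at 0.95 m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from shapely.geometry import LineString, Point

from .errors import UndefinedRateError
from .hough import Segment
from .stem_region import GridSystem, StemInterval

DEFAULT_MATCH_DIST_PX = 5.0
_N_SAMPLE = 32


@dataclass
class GroundTruth:
    """Annotated main stems of one image: polylines of (col, row) vertices."""

    image_id: str
    main_stems: list          # list of [[col,row], ...]

    @staticmethod
    def from_json(text: str) -> "GroundTruth":
        d = json.loads(text)
        return GroundTruth(image_id=str(d["image"]), main_stems=d["main_stems"])

    def to_json(self) -> str:
        return json.dumps({"image": self.image_id,
                           "main_stems": self.main_stems}, indent=1)


@dataclass
class EvalCounts:
    FN: int = 0
    TP: int = 0
    FP: int = 0
    SD: int = 0
    n_main_stems: int = 0
    n_detected: int = 0

    def __post_init__(self) -> None:
        assert self.FN + self.TP == self.n_main_stems
        assert self.FP + self.SD == self.n_detected


def _segment_points(seg: Segment) -> np.ndarray:
    t = np.linspace(0.0, 1.0, _N_SAMPLE)[:, None]
    return np.asarray(seg.p0, float) + t * (np.asarray(seg.p1, float)
                                            - np.asarray(seg.p0, float))


def _mean_dist(seg: Segment, polyline: LineString) -> float:
    return float(np.mean([polyline.distance(Point(p))
                          for p in _segment_points(seg)]))


def _stem_in_interval(polyline, interval: StemInterval, grid: GridSystem) -> bool:
    rows = [p[1] for p in polyline]
    return (grid.hist_row(max(rows)) >= interval.lo
            and grid.hist_row(min(rows)) <= interval.hi)


def _seg_in_interval(seg: Segment, interval: StemInterval, grid: GridSystem) -> bool:
    r0, r1 = grid.hist_row(seg.p0[1]), grid.hist_row(seg.p1[1])
    return r1 >= interval.lo and r0 <= interval.hi


def count_events(truth: GroundTruth, segs: list[Segment],
                 interval: StemInterval | None = None,
                 grid: GridSystem | None = None,
                 match_dist_px: float = DEFAULT_MATCH_DIST_PX) -> EvalCounts:
    """Count FN/TP/FP/SD for one image.

    When ``interval`` and ``grid`` are given, only stems and segments whose
    rows intersect the valley region [lo, hi] are considered; with
    ``interval=None`` the whole frame is evaluated (the relaxed setting).
    """
    restrict = interval is not None and grid is not None
    stems = [s for s in truth.main_stems
             if not restrict or _stem_in_interval(s, interval, grid)]
    dets = [s for s in segs
            if not restrict or _seg_in_interval(s, interval, grid)]

    lines = [LineString(s) for s in stems]
    covered = [False] * len(lines)
    sd = 0
    for seg in dets:
        dists = [_mean_dist(seg, ln) for ln in lines]
        if dists and min(dists) <= match_dist_px:
            sd += 1
            covered[int(np.argmin(dists))] = True
    tp = sum(covered)
    return EvalCounts(FN=len(lines) - tp, TP=tp, FP=len(dets) - sd, SD=sd,
                      n_main_stems=len(lines), n_detected=len(dets))


@dataclass
class RateSummary:
    fnr: float
    tpr: float
    er: float
    ac: float


def rates(batch: list[EvalCounts]) -> RateSummary:
    """Aggregate batch rates as fractions in [0, 1]."""
    stems = sum(c.n_main_stems for c in batch)
    dets = sum(c.n_detected for c in batch)
    if stems == 0 or dets == 0:
        raise UndefinedRateError("zero main stems or zero detections in batch")
    return RateSummary(
        fnr=sum(c.FN for c in batch) / stems,
        tpr=sum(c.TP for c in batch) / stems,
        er=sum(c.FP for c in batch) / dets,
        ac=sum(c.SD for c in batch) / dets,
    )


def pct(x: float, decimals: int = 1) -> float:
    """Percentage rounded half-up, matching report presentation."""
    q = Decimal(10) ** -decimals
    return float(Decimal(x * 100).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Published per-growth-phase detection counts for a cherry and an ordinary
# greenhouse tomato cultivar (Kinect at 0.9-1.0 m, indoor).  Used as the
# worked example for the rate definitions and as a regression fixture.

CHERRY_PHASE_COUNTS = [
    EvalCounts(FN=2, TP=9, FP=0, SD=14, n_main_stems=11, n_detected=14),
    EvalCounts(FN=5, TP=12, FP=0, SD=16, n_main_stems=17, n_detected=16),
    EvalCounts(FN=4, TP=18, FP=1, SD=32, n_main_stems=22, n_detected=33),
]

ORDINARY_PHASE_COUNTS = [
    EvalCounts(FN=5, TP=14, FP=1, SD=17, n_main_stems=19, n_detected=18),
    EvalCounts(FN=9, TP=15, FP=0, SD=21, n_main_stems=24, n_detected=21),
    EvalCounts(FN=10, TP=53, FP=3, SD=75, n_main_stems=63, n_detected=78),
    EvalCounts(FN=18, TP=29, FP=5, SD=43, n_main_stems=47, n_detected=48),
]


def report_markdown(per_phase: dict[str, list[EvalCounts]]) -> str:
    """Emit a per-phase + total rate table in Markdown."""
    out = ["| variety | phase | stems | detected | FNR | TPR | ER | Ac |",
           "|---|---|---|---|---|---|---|---|"]
    for variety, phases in per_phase.items():
        for i, c in enumerate(phases, 1):
            r = rates([c])
            out.append(f"| {variety} | {i} | {c.n_main_stems} | {c.n_detected} |"
                       f" {pct(r.fnr)}% | {pct(r.tpr)}% | {pct(r.er)}% | {pct(r.ac)}% |")
        r = rates(phases)
        out.append(f"| {variety} | total | {sum(c.n_main_stems for c in phases)} |"
                   f" {sum(c.n_detected for c in phases)} |"
                   f" {pct(r.fnr)}% | {pct(r.tpr)}% | {pct(r.er)}% | {pct(r.ac)}% |")
    return "\n".join(out)
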