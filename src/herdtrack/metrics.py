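"""CLEAR-MOT and identity evaluation: MOTA, MOTP, IDF1, MT/ML/FM and counts.

The per-frame matching follows the CLEAR-MOT protocol: correspondences
persisting from the previous frame are kept while their IoU stays at or
above the threshold; the remaining ground-truth / hypothesis boxes are then
paired by an optimal bipartite assignment maximizing total IoU among pairs
meeting the threshold.  An identity switch is counted when a ground-truth
trajectory's matched hypothesis id differs from its *last* matched id,
including across fully-unmatched gaps.

MOTA = 1 - (FN + FP + IDSW) / GT  (may be negative).
MOTP = mean IoU over all matches, reported on the [0, 1] IoU scale.
IDF1 = 2 IDTP / (2 IDTP + IDFP + IDFN) from a single global
trajectory-level assignment between ground-truth and hypothesis ids.
FM counts interruptions: maximal unmatched gaps strictly inside a
ground-truth trajectory's lifespan with matched frames on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import Detection, FrameTable

DEFAULT_IOU_THRESHOLD = 0.5


def iou(a: Detection, b: Detection) -> float:
    """Intersection over union of two boxes with half-open semantics."""
    ax0, ay0 = a.left, a.top
    bx0, by0 = b.left, b.top
    iw = min(ax0 + a.size[0], bx0 + b.size[0]) - max(ax0, bx0)
    ih = min(ay0 + a.size[1], by0 + b.size[1]) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.size[0] * a.size[1] + b.size[0] * b.size[1] - inter
    return inter / union


@dataclass
class EvalReport:
    """All counts and derived metrics for one gt/hypothesis pair."""

    num_frames: int = 0
    num_gt: int = 0
    fp: int = 0
    fn: int = 0
    idsw: int = 0
    num_matches: int = 0
    sum_iou: float = 0.0
    idtp: int = 0
    idfp: int = 0
    idfn: int = 0
    mt: int = 0
    ml: int = 0
    fm: int = 0
    num_gt_trajectories: int = 0
    per_frame: list = field(default_factory=list)

    @property
    def mota(self) -> float:
        if self.num_gt == 0:
            raise ZeroDivisionError("MOTA undefined: no ground-truth objects")
        return 1.0 - (self.fn + self.fp + self.idsw) / self.num_gt

    @property
    def motp(self) -> float:
        return self.sum_iou / self.num_matches if self.num_matches else float("nan")

    @property
    def idf1(self) -> float:
        denom = 2 * self.idtp + self.idfp + self.idfn
        return 2 * self.idtp / denom if denom else float("nan")

    def summary(self) -> dict:
        return dict(
            MOTA=self.mota, MOTP=self.motp, IDF1=self.idf1,
            MT=self.mt, ML=self.ml, FM=self.fm,
            FP=self.fp, FN=self.fn, IDsw=self.idsw,
            GT=self.num_gt, matches=self.num_matches,
        )


def _match_frames(
    gt: FrameTable, hyp: FrameTable, threshold: float
) -> dict[int, list[tuple[Detection, Detection, float]]]:
    """Per-frame correspondences under the persistence + assignment rule."""
    frames = sorted(set(gt.frames()) | set(hyp.frames()))
    last_match: dict[int, int] = {}  # gt id -> hyp id from the prior frame
    out: dict[int, list[tuple[Detection, Detection, float]]] = {}
    for f in frames:
        g = gt.in_frame(f)
        h = hyp.in_frame(f)
        matches: list[tuple[Detection, Detection, float]] = []
        g_left, h_left = list(g), list(h)

        # 1. keep persisting pairs whose IoU still clears the gate
        hyp_by_id = {d.id: d for d in h_left}
        for gd in list(g_left):
            hid = last_match.get(gd.id)
            if hid is not None and hid in hyp_by_id:
                hd = hyp_by_id[hid]
                v = iou(gd, hd)
                if v >= threshold:
                    matches.append((gd, hd, v))
                    g_left.remove(gd)
                    h_left.remove(hd)
                    del hyp_by_id[hid]

        # 2. optimal assignment on the rest, maximizing total IoU
        if g_left and h_left:
            cost = np.zeros((len(g_left), len(h_left)))
            for i, gd in enumerate(g_left):
                for j, hd in enumerate(h_left):
                    v = iou(gd, hd)
                    if v >= threshold:
                        cost[i, j] = -v
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < 0:
                    matches.append((g_left[i], h_left[j], -cost[i, j]))

        out[f] = matches
        for gd, hd, _ in matches:
            last_match[gd.id] = hd.id
    return out


def clear_mot(
    gt: FrameTable,
    hyp: FrameTable,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> EvalReport:
    """CLEAR-MOT counts and MOTA/MOTP for a gt/hypothesis table pair."""
    if len(gt) == 0 and len(hyp) > 0:
        raise ZeroDivisionError("MOTA undefined: no ground-truth objects")
    rep = EvalReport()
    matches = _match_frames(gt, hyp, iou_threshold)
    last_hyp: dict[int, int] = {}  # gt id -> last matched hyp id, ever
    for f in sorted(set(gt.frames()) | set(hyp.frames())):
        g, h = gt.in_frame(f), hyp.in_frame(f)
        ms = matches.get(f, [])
        fn = len(g) - len(ms)
        fp = len(h) - len(ms)
        idsw = 0
        for gd, hd, v in ms:
            prev = last_hyp.get(gd.id)
            if prev is not None and prev != hd.id:
                idsw += 1
            last_hyp[gd.id] = hd.id
            rep.sum_iou += v
        rep.num_matches += len(ms)
        rep.fn += fn
        rep.fp += fp
        rep.idsw += idsw
        rep.num_gt += len(g)
        rep.num_frames += 1
        rep.per_frame.append(dict(frame=f, gt=len(g), fn=fn, fp=fp, idsw=idsw,
                                  matches=len(ms)))
    return rep


def idf1(
    gt: FrameTable,
    hyp: FrameTable,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[int, int, int, float]:
    """Identity metrics from a global trajectory-level assignment.

    gt and hypothesis identities are paired once for the whole sequence to
    maximize the number of frames on which the paired boxes agree (IoU at
    or above the threshold); IDTP is that total, IDFN and IDFP the
    uncovered gt / hypothesis box counts.
    """
    if len(gt) == 0 and len(hyp) > 0:
        raise ZeroDivisionError("IDF1 undefined: no ground-truth objects")
    gt_by_id = gt.by_id()
    hyp_by_id = hyp.by_id()
    gids, hids = sorted(gt_by_id), sorted(hyp_by_id)
    overlap = np.zeros((len(gids), len(hids)), dtype=int)
    for i, gid in enumerate(gids):
        g_frames = {d.frame: d for d in gt_by_id[gid]}
        for j, hid in enumerate(hids):
            n = 0
            for hd in hyp_by_id[hid]:
                gd = g_frames.get(hd.frame)
                if gd is not None and iou(gd, hd) >= iou_threshold:
                    n += 1
            overlap[i, j] = n
    idtp = 0
    if overlap.size:
        ri, ci = linear_sum_assignment(-overlap)
        idtp = int(overlap[ri, ci].sum())
    n_gt = sum(len(v) for v in gt_by_id.values())
    n_hyp = sum(len(v) for v in hyp_by_id.values())
    idfn = n_gt - idtp
    idfp = n_hyp - idtp
    denom = 2 * idtp + idfp + idfn
    return idtp, idfp, idfn, (2 * idtp / denom if denom else float("nan"))


def trajectory_stats(
    gt: FrameTable,
    hyp: FrameTable,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[int, int, int]:
    """MT / ML / FM over ground-truth trajectories.

    Tracked fraction = matched frames / trajectory length; MT requires
    >= 0.8, ML is < 0.2.  FM counts interior matched->unmatched->matched
    interruptions.
    """
    matches = _match_frames(gt, hyp, iou_threshold)
    matched_gt: dict[int, set[int]] = {}
    for f, ms in matches.items():
        for gd, _, _ in ms:
            matched_gt.setdefault(gd.id, set()).add(f)
    mt = ml = fm = 0
    for gid, dets in gt.by_id().items():
        frames = sorted(d.frame for d in dets)
        got = matched_gt.get(gid, set())
        frac = sum(1 for f in frames if f in got) / len(frames)
        if frac >= 0.8:
            mt += 1
        elif frac < 0.2:
            ml += 1
        # interruptions: unmatched runs with matched frames on both sides
        pattern = [f in got for f in frames]
        in_gap = False
        seen_match = False
        for p in pattern:
            if p:
                if in_gap and seen_match:
                    fm += 1
                in_gap = False
                seen_match = True
            elif seen_match:
                in_gap = True
    return mt, ml, fm


def evaluate(
    gt: FrameTable,
    hyp: FrameTable,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> EvalReport:
    """Full report: CLEAR-MOT counts, identity metrics and MT/ML/FM."""
    rep = clear_mot(gt, hyp, iou_threshold)
    rep.idtp, rep.idfp, rep.idfn, _ = idf1(gt, hyp, iou_threshold)
    rep.mt, rep.ml, rep.fm = trajectory_stats(gt, hyp, iou_threshold)
    rep.num_gt_trajectories = len(gt.by_id())
    return rep


def format_report(rep: EvalReport) -> str:
    """Aligned table of the main metrics, percentages where customary."""
    s = rep.summary()
    lines = [
        f"{'MOTA':>6}  {s['MOTA'] * 100:6.1f} %",
        f"{'MOTP':>6}  {s['MOTP'] * 100:6.1f} %",
        f"{'IDF1':>6}  {s['IDF1'] * 100:6.1f} %",
        f"{'MT':>6}  {s['MT']:6d}",
        f"{'ML':>6}  {s['ML']:6d}",
        f"{'FM':>6}  {s['FM']:6d}",
        f"{'FP':>6}  {s['FP']:6d}",
        f"{'FN':>6}  {s['FN']:6d}",
        f"{'IDsw':>6}  {s['IDsw']:6d}",
    ]
    return "\n".join(lines)
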