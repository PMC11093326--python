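"""Independent reference implementations used only by the tests.

``BruteForceEval`` re-implements the CLEAR-MOT / identity evaluation
protocol with exhaustive enumeration instead of the Hungarian solver: per
frame, after keeping persisting correspondences, every injective pairing of
remaining ground-truth and hypothesis boxes is enumerated and the one with
maximal total IoU is taken (feasible pairs only).  ``kalman_filter`` is a
textbook linear-Gaussian filter used as the analytic oracle for the
particle filter's Kalman limit.

Feasible only for tiny instances (<= ~5 boxes per frame), which is the
point: the production code must agree with it exactly on random small
scenarios.
"""

from __future__ import annotations

import itertools

import numpy as np

from herdtrack.datamodel import FrameTable
from herdtrack.metrics import iou


def _best_assignment(gts, hyps, threshold):
    """Exhaustive max-total-IoU injective pairing; returns list of (g, h, iou)."""
    n, m = len(gts), len(hyps)
    best, best_score = [], 0.0
    small, large, swapped = (range(n), range(m), False) if n <= m else (
        range(m), range(n), True)
    k = len(list(small))
    for subset in itertools.permutations(large, k):
        pairs = []
        score = 0.0
        for a, b in zip(small, subset):
            i, j = (a, b) if not swapped else (b, a)
            v = iou(gts[i], hyps[j])
            if v >= threshold:
                pairs.append((gts[i], hyps[j], v))
                score += v
        if score > best_score:
            best, best_score = pairs, score
    return best


class BruteForceEval:
    """Full evaluation via exhaustive per-frame and per-identity search."""

    def __init__(self, gt: FrameTable, hyp: FrameTable, threshold: float = 0.5):
        self.gt, self.hyp, self.threshold = gt, hyp, threshold
        self._frame_matches = self._match_all()

    def _match_all(self):
        frames = sorted(set(self.gt.frames()) | set(self.hyp.frames()))
        prev: dict[int, int] = {}
        out = {}
        for f in frames:
            g = self.gt.in_frame(f)
            h = self.hyp.in_frame(f)
            kept = []
            g_rest, h_rest = list(g), list(h)
            for gd in list(g_rest):
                hid = prev.get(gd.id)
                cand = [hd for hd in h_rest if hd.id == hid]
                if cand and iou(gd, cand[0]) >= self.threshold:
                    kept.append((gd, cand[0], iou(gd, cand[0])))
                    g_rest.remove(gd)
                    h_rest.remove(cand[0])
            kept += _best_assignment(g_rest, h_rest, self.threshold)
            out[f] = kept
            for gd, hd, _ in kept:
                prev[gd.id] = hd.id
        return out

    def clear_mot_counts(self):
        fn = fp = idsw = num_gt = nmatch = 0
        sum_iou = 0.0
        last: dict[int, int] = {}
        for f in sorted(set(self.gt.frames()) | set(self.hyp.frames())):
            g, h = self.gt.in_frame(f), self.hyp.in_frame(f)
            ms = self._frame_matches[f]
            fn += len(g) - len(ms)
            fp += len(h) - len(ms)
            for gd, hd, v in ms:
                if gd.id in last and last[gd.id] != hd.id:
                    idsw += 1
                last[gd.id] = hd.id
                sum_iou += v
            nmatch += len(ms)
            num_gt += len(g)
        return dict(fn=fn, fp=fp, idsw=idsw, num_gt=num_gt,
                    num_matches=nmatch, sum_iou=sum_iou)

    def idf1_counts(self):
        gt_by = self.gt.by_id()
        hyp_by = self.hyp.by_id()
        gids, hids = sorted(gt_by), sorted(hyp_by)

        def overlap(gid, hid):
            gmap = {d.frame: d for d in gt_by[gid]}
            return sum(
                1 for hd in hyp_by[hid]
                if hd.frame in gmap and iou(gmap[hd.frame], hd) >= self.threshold
            )

        best = 0
        k = min(len(gids), len(hids))
        for gsub in itertools.permutations(gids, k):
            for hsub in itertools.permutations(hids, k):
                best = max(best, sum(overlap(a, b) for a, b in zip(gsub, hsub)))
        n_gt = sum(len(v) for v in gt_by.values())
        n_hyp = sum(len(v) for v in hyp_by.values())
        return dict(idtp=best, idfn=n_gt - best, idfp=n_hyp - best)

    def trajectory_counts(self):
        matched: dict[int, set[int]] = {}
        for f, ms in self._frame_matches.items():
            for gd, _, _ in ms:
                matched.setdefault(gd.id, set()).add(f)
        mt = ml = fm = 0
        for gid, dets in self.gt.by_id().items():
            frames = sorted(d.frame for d in dets)
            hits = [f in matched.get(gid, set()) for f in frames]
            frac = sum(hits) / len(hits)
            if frac >= 0.8:
                mt += 1
            elif frac < 0.2:
                ml += 1
            # count maximal False-runs bounded by True on both sides
            for a in range(len(hits)):
                if (hits[a] is False and a > 0 and hits[a - 1]
                        and any(hits[a:])):
                    fm += 1
        return dict(mt=mt, ml=ml, fm=fm)


def kalman_filter(F, H, Q, R, x0, P0, observations):
    """Plain Kalman filter; returns the filtered state means."""
    x, P = np.array(x0, dtype=float), np.array(P0, dtype=float)
    out = []
    eye = np.eye(len(x))
    for z in observations:
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.asarray(z) - H @ x)
        P = (eye - K @ H) @ P
        out.append(x.copy())
    return np.array(out)
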