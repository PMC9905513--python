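"""Independent oracles shared by the unit and acceptance tests.

These deliberately re-derive results by the most literal route possible
(double loops, direct set arithmetic) and must stay independent of the
production implementations they check.
"""

from math import sqrt

import numpy as np


def ncc_bruteforce(scene: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Literal double-loop transcription of the correlation-coefficient map.

    For every window position, subtract the window mean and template mean,
    form the cross-product sum and divide by the root product of the two sums
    of squared deviations.  Zero-variance windows score 0.
    """
    I = np.asarray(scene, dtype=np.float64)
    R = np.asarray(template, dtype=np.float64)
    M, N = I.shape
    m, n = R.shape
    R_bar = R.mean()
    ss_R = ((R - R_bar) ** 2).sum()
    out = np.zeros((M - m + 1, N - n + 1))
    for r in range(M - m + 1):
        for s in range(N - n + 1):
            w = I[r : r + m, s : s + n]
            w_bar = w.mean()
            num = ((w - w_bar) * (R - R_bar)).sum()
            Z = sqrt(((w - w_bar) ** 2).sum() * ss_R)
            out[r, s] = 0.0 if Z == 0.0 else num / Z
    return out


def nearest_mean_bruteforce(xy: np.ndarray) -> float:
    """Mean nearest-neighbour distance of a point set by direct enumeration."""
    xy = np.asarray(xy, dtype=np.float64)
    n = len(xy)
    nn = np.empty(n)
    for i in range(n):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        nn[i] = d.min()
    return float(nn.mean())


def match_detections_to_truth(detections, truth, tol_px=5):
    """Greedy anchor matching; returns (n_matched, n_false_positive)."""
    unmatched = {
        (t["template_id"], t["row"], t["col"]) for t in truth
    }
    false_pos = 0
    for det in detections:
        hit = None
        for tid, row, col in unmatched:
            if (
                det.template_id == tid
                and abs(det.anchor[0] - row) <= tol_px
                and abs(det.anchor[1] - col) <= tol_px
            ):
                hit = (tid, row, col)
                break
        if hit is None:
            false_pos += 1
        else:
            unmatched.remove(hit)
    return len(truth) - len(unmatched), false_pos
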