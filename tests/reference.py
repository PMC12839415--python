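"""Independent brute-force reference implementations used as test oracles.

These deliberately favour clarity over speed and recompute everything from
scratch at each step; they share no code with the package internals.
"""

import numpy as np

from ocatscreen.geometry import DEFAULT_GEOMETRY, deg_to_px, px_to_deg


def dispersion_px(x, y):
    """Max pairwise distance by explicit double loop."""
    best = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            d = float(np.hypot(x[i] - x[j], y[i] - y[j]))
            if d > best:
                best = d
    return best


def idt_reference(t, x, y, valid, thresh_deg=1.0, min_dur_ms=100.0,
                  onset_deg_s=60.0, geometry=DEFAULT_GEOMETRY):
    """Exhaustive window-scan I-DT over one recording.

    Returns (fixations, saccades) where fixations are (t_start, t_end,
    dispersion_px) and saccades are (t_start, t_end) tuples, mirroring the
    algorithmic contract: dispersion windows grown from the minimum
    duration, segments split at invalid samples, saccades only between
    consecutive fixations with centroid displacement above threshold and at
    least one intervening sample, delimited by the peak-anchored velocity
    criterion.
    """
    thresh_px = float(deg_to_px(thresh_deg, geometry))
    fixations, saccades = [], []
    n = len(t)
    s = 0
    while s < n:
        if not valid[s]:
            s += 1
            continue
        e = s
        while e < n and valid[e]:
            e += 1
        ts, xs, ys = t[s:e], x[s:e], y[s:e]
        fx = []  # (i, j) in segment coordinates
        i = 0
        m = len(ts)
        while i < m:
            j = None
            for cand in range(i, m):
                if ts[cand] >= ts[i] + min_dur_ms:
                    j = cand
                    break
            if j is None:
                break
            if dispersion_px(xs[i : j + 1], ys[i : j + 1]) <= thresh_px:
                while j + 1 < m and dispersion_px(xs[i : j + 2], ys[i : j + 2]) <= thresh_px:
                    j += 1
                fx.append((i, j))
                i = j + 1
            else:
                i += 1
        for (i, j) in fx:
            fixations.append((float(ts[i]), float(ts[j]),
                              dispersion_px(xs[i : j + 1], ys[i : j + 1])))
        for a in range(len(fx) - 1):
            ja = fx[a][1]
            ib = fx[a + 1][0]
            if ib - ja < 2:
                continue
            ca = (np.mean(xs[fx[a][0] : ja + 1]), np.mean(ys[fx[a][0] : ja + 1]))
            cb = (np.mean(xs[ib : fx[a + 1][1] + 1]), np.mean(ys[ib : fx[a + 1][1] + 1]))
            if px_to_deg(np.hypot(cb[0] - ca[0], cb[1] - ca[1]), geometry) <= thresh_deg:
                continue
            vel = [
                float(px_to_deg(np.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k]), geometry)
                      / ((ts[k + 1] - ts[k]) / 1000.0))
                for k in range(ja, ib)
            ]
            peak = int(np.argmax(vel))
            if vel[peak] > onset_deg_s:
                lo = peak
                while lo > 0 and vel[lo - 1] > onset_deg_s:
                    lo -= 1
                hi = peak
                while hi < len(vel) - 1 and vel[hi + 1] > onset_deg_s:
                    hi += 1
                saccades.append((float(ts[ja + lo]), float(ts[ja + hi + 1])))
            else:
                saccades.append((float(ts[ja]), float(ts[ib])))
        s = e
    return fixations, saccades


def average_precision_reference(y_true, scores):
    """AP by explicit enumeration over every distinct score threshold."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    thresholds = sorted(set(s), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    n_pos = int(y.sum())
    for th in thresholds:
        pred = s >= th
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def blink_runs_reference(valid, dt_ms, min_ms, max_ms):
    """Run-length scan for blink-range invalid runs."""
    runs = []
    run = 0
    for v in list(valid) + [True]:
        if not v:
            run += 1
        else:
            if run and min_ms <= run * dt_ms <= max_ms:
                runs.append(run)
            run = 0
    return runs
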