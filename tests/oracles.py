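"""Brute-force reference implementations used to cross-check the extractors.

Each oracle applies the same extraction rule as the library but by direct
exhaustive scanning (per-sample loops, np.polyfit per window) instead of the
vectorised running-sum path, so agreement is a genuine dual-route check.
"""

import numpy as np


def brute_max_load(force):
    """Largest force and first index attaining it, by plain loop."""
    best_i, best_f = 0, force[0]
    for i, f in enumerate(force):
        if f > best_f:
            best_i, best_f = i, f
    return float(best_f), best_i


def brute_failure_load(force, max_index, endpoint_index):
    """Last local maximum in [max_index, endpoint_index], by plain loop."""
    best = max_index
    for i in range(max(max_index, 1), endpoint_index):
        if force[i] >= force[i - 1] and force[i] >= force[i + 1]:
            best = i
    return float(force[best]), best


def brute_yield(curve, region, k_sd=2.0, rel_floor=0.005):
    """First window centre whose polyfit slope falls below the yield
    threshold, scanning forward from the elastic-region end."""
    d, f = curve.displacement, curve.force
    max_idx = int(np.argmax(f))
    wl = region.local_window
    hl = wl // 2
    thresh = region.local_slope_mean - max(k_sd * region.local_slope_sd,
                                           rel_floor * region.local_slope_mean)
    c0 = max(hl, region.end_index - hl + 1)
    c1 = min(max_idx - hl, len(f) - 1 - hl)
    for c in range(c0, c1 + 1):
        slope = np.polyfit(d[c - hl:c + hl + 1], f[c - hl:c + hl + 1], 1)[0]
        if slope < thresh:
            return float(f[c]), c, False
    return float(f[max_idx]), max_idx, True


def brute_windowed_mean(force, window):
    """Centred moving average with symmetrically shrunken edge windows."""
    n = len(force)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        hw = min(half, i, n - 1 - i)
        out[i] = np.mean(force[i - hw:i + hw + 1])
    return out


def brute_endpoint(force, displacement, drop_fraction=0.5,
                   max_displacement=2.0, min_peak_force=20.0):
    """First sample violating either endpoint criterion, by plain loop."""
    runmax = -np.inf
    for i in range(len(force)):
        runmax = max(runmax, force[i])
        if runmax > min_peak_force and force[i] <= (1 - drop_fraction) * runmax:
            return i, "force_drop"
        if displacement[i] > max_displacement:
            return i, "displacement"
    return len(force) - 1, "end_of_data"
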