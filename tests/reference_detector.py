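"""Literal per-sample reference implementation of the microsaccade detector.

Written as plain Python loops, rule by rule, so it can serve as an
independent oracle for the vectorized detector: moving-average derivative
with shrunken edge windows, undefined velocity near missing-pupil samples,
median-based robust sigma, elliptical lambda*sigma criterion, minimum
duration, merge gap, and the blink/saccade reclassification rules.
"""

import math
import statistics


def ref_velocity(x, y, pupil_valid, dt_ms, window):
    n = len(x)
    k = (window - 1) // 2
    dt_s = dt_ms / 1000.0

    def deriv(arr, i):
        if i == 0:
            return (arr[1] - arr[0]) / dt_s
        if i == n - 1:
            return (arr[n - 1] - arr[n - 2]) / dt_s
        ke = min(k, i, n - 1 - i)
        total = 0.0
        for j in range(1, ke + 1):
            total += arr[i + j] - arr[i - j]
        return total / (dt_s * ke * (ke + 1))

    vx = [deriv(x, i) for i in range(n)]
    vy = [deriv(y, i) for i in range(n)]
    for i in range(n):
        near_bad = any(not pupil_valid[j]
                       for j in range(max(0, i - k), min(n, i + k + 1)))
        if near_bad:
            vx[i] = math.nan
            vy[i] = math.nan
    speed = [math.hypot(vx[i], vy[i]) for i in range(n)]
    accel = [0.0] * n
    for i in range(n):
        if i == 0:
            accel[i] = (speed[1] - speed[0]) / dt_s
        elif i == n - 1:
            accel[i] = (speed[n - 1] - speed[n - 2]) / dt_s
        else:
            accel[i] = (speed[i + 1] - speed[i - 1]) / (2.0 * dt_s)
    return vx, vy, speed, accel


def ref_sigma(values):
    finite = [v for v in values if math.isfinite(v)]
    med = statistics.median(finite)
    med_sq = statistics.median([v * v for v in finite])
    var = med_sq - med * med
    return math.sqrt(var) if var > 0 else 0.0


def ref_detect_microsaccades(trace, params):
    """Event list as (kind, onset_idx, offset_idx) triples."""
    x, y = list(trace.x_deg), list(trace.y_deg)
    valid = list(trace.pupil_valid)
    n = len(x)
    dt = trace.dt_ms
    vx, vy, speed, accel = ref_velocity(x, y, valid, dt,
                                        params.velocity_window_samples)
    eta_x = params.lambda_ * ref_sigma(vx)
    eta_y = params.lambda_ * ref_sigma(vy)
    if eta_x <= 0 or eta_y <= 0:
        return []

    crit = []
    for i in range(n):
        if math.isnan(vx[i]) or math.isnan(vy[i]):
            crit.append(False)
        else:
            crit.append((vx[i] / eta_x) ** 2 + (vy[i] / eta_y) ** 2 > 1.0)

    # maximal runs of candidates
    runs = []
    i = 0
    while i < n:
        if crit[i]:
            j = i
            while j + 1 < n and crit[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    runs = [(a, b) for a, b in runs if (b - a) * dt >= params.min_duration_ms]

    gap = params.merge_gap_ms / dt
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    invalid_runs = []
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j + 1 < n and not valid[j + 1]:
                j += 1
            invalid_runs.append((i, j))
            i = j + 1
        else:
            i += 1

    events = []
    for a, b in merged:
        overlaps_blink = any(s <= b and e >= a for s, e in invalid_runs)
        if overlaps_blink:
            kind = "blink"
        elif _ref_is_saccade(speed, accel, a, b, params, dt):
            kind = "saccade"
        else:
            kind = "microsaccade"
        events.append((kind, a, b))
    return events


def _ref_is_saccade(speed, accel, a, b, params, dt):
    fast = [(not math.isnan(speed[i]))
            and speed[i] > params.saccade_velocity_deg_s
            for i in range(a, b + 1)]
    longest = -1.0
    i = 0
    while i < len(fast):
        if fast[i]:
            j = i
            while j + 1 < len(fast) and fast[j + 1]:
                j += 1
            longest = max(longest, (j - i) * dt)
            i = j + 1
        else:
            i += 1
    if longest < params.min_duration_ms:
        return False
    finite_acc = [abs(accel[i]) for i in range(a, b + 1)
                  if math.isfinite(accel[i])]
    peak_a = max(finite_acc) if finite_acc else 0.0
    return peak_a > params.saccade_accel_deg_s2
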