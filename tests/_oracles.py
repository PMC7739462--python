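"""Independent brute-force re-implementations of the ten per-minute
statistics, written as naive Python loops with no shared code with the
package. Used to freeze expected values and for the oracle-equivalence
suite."""

import math


def oracle_basic_stats(x):
    n = len(x)
    s_max = x[0]
    s_min = x[0]
    total = 0.0
    for v in x:
        if v > s_max:
            s_max = v
        if v < s_min:
            s_min = v
        total += v
    mean = total / n
    ss = 0.0
    for v in x:
        ss += (v - mean) ** 2
    return s_max, s_min, mean, ss / n


def oracle_zero_cross_count(x):
    mean = sum(x) / len(x)
    count = 0
    last_sign = 0
    for v in x:
        d = v - mean
        if d == 0:
            continue
        sign = 1 if d > 0 else -1
        if last_sign != 0 and sign != last_sign:
            count += 1
        last_sign = sign
    return count


def oracle_regression(x):
    n = len(x)
    st = sx = stt = stx = 0.0
    for t, v in enumerate(x):
        st += t
        sx += v
        stt += t * t
        stx += t * v
    slope = (n * stx - st * sx) / (n * stt - st * st)
    bias = (sx - slope * st) / n
    return slope, bias, abs(slope)


def oracle_correlation(x):
    n = len(x)
    mean_t = (n - 1) / 2.0
    mean_x = sum(x) / n
    num = den_t = den_x = 0.0
    for t, v in enumerate(x):
        num += (t - mean_t) * (v - mean_x)
        den_t += (t - mean_t) ** 2
        den_x += (v - mean_x) ** 2
    if den_x == 0:
        return 0.0
    return num / math.sqrt(den_t * den_x)


def oracle_delta_index(x, block=12):
    means = []
    for k in range(len(x) // block):
        s = 0.0
        for v in x[k * block : (k + 1) * block]:
            s += v
        means.append(s / block)
    diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
    return sum(diffs) / len(diffs)


def oracle_feature_vector(x):
    s_max, s_min, s_mean, s_vari = oracle_basic_stats(x)
    slope, bias, abslope = oracle_regression(x)
    return (
        s_max,
        s_min,
        s_mean,
        s_vari,
        oracle_correlation(x),
        oracle_zero_cross_count(x),
        slope,
        abslope,
        bias,
        oracle_delta_index(x),
    )
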