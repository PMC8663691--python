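"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with explicit Python-level summation, separate from
the vectorized code paths it validates.
"""

from __future__ import annotations

import math

from scipy import stats


def npl_loop(values, duration) -> float:
    total = 0.0
    for a, b in zip(values[:-1], values[1:]):
        total += abs(b - a)
    return total / duration


def rms_loop(values) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def p2p_loop(values) -> float:
    return max(values) - min(values)


def icc_consistency_loop(matrix, alpha=0.05):
    """ICC(3,1) and its F-pivot CI from explicit sums of squares."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    row_means = [sum(row) / k for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
    f_obs = ms_rows / ms_error
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return icc, lo, hi


def ols_r2_closed_form(x, y):
    """R^2 from the raw moment sums, no library calls."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return num * num / den
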