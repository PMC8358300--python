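"""Independent brute-force recomputations of the stabilometric measures.

Literal transcriptions of the defining formulas using plain Python loops,
kept deliberately separate from the package's vectorized implementations
so the two code paths can be compared on small inputs.
"""
import math

from scipy import stats


def brute_mean_distance(x):
    return sum(abs(v) for v in x) / len(x)


def brute_mean_velocity(x, fs):
    total = 0.0
    for a, b in zip(x[:-1], x[1:]):
        total += abs(b - a)
    duration = (len(x) - 1) / fs
    return total / duration


def brute_ellipse_area(ap, ml, quantile=0.95):
    n = len(ap)
    mean_ap = sum(ap) / n
    mean_ml = sum(ml) / n
    s_aa = sum((a - mean_ap) ** 2 for a in ap) / (n - 1)
    s_mm = sum((m - mean_ml) ** 2 for m in ml) / (n - 1)
    s_am = sum((a - mean_ap) * (m - mean_ml) for a, m in zip(ap, ml)) / (n - 1)
    det = s_aa * s_mm - s_am**2
    if det <= 0:
        return 0.0
    fcrit = stats.f.ppf(quantile, 2, n - 2)
    return 2.0 * math.pi * fcrit * math.sqrt(det)


def brute_mean_frequency(x, fs):
    md = brute_mean_distance(x)
    if md == 0:
        return float("nan")
    return brute_mean_velocity(x, fs) / (4.0 * math.sqrt(2.0) * md)


def enumerate_signed_rank_p(d):
    """Exact two-sided signed-rank p by explicit 2^n enumeration.

    Works directly on the differences: midranks of |d| (zeros removed),
    then every sign pattern; two-sided p = 2*min(tail) capped at 1.
    """
    dnz = [v for v in d if v != 0]
    n = len(dnz)
    absd = [abs(v) for v in dnz]
    ranks = []
    for v in absd:
        less = sum(1 for u in absd if u < v)
        equal = sum(1 for u in absd if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    w_obs = sum(r for v, r in zip(dnz, ranks) if v > 0)
    w_all = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        w_all.append(w)
    total = len(w_all)
    p_le = sum(1 for w in w_all if w <= w_obs + 1e-9) / total
    p_ge = sum(1 for w in w_all if w >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
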