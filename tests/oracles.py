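"""Independent brute-force oracles used to cross-check production code.

Deliberately naive: plain dictionary counting and literal formulas, no
shared code with the package internals.
"""

import itertools
import math


def naive_word_counts(seq, k):
    """Overlapping k-mer counts by literal slicing; windows with non-ACGT
    characters are skipped."""
    counts = {}
    valid = 0
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if any(c not in "ACGT" for c in w):
            continue
        valid += 1
        counts[w] = counts.get(w, 0) + 1
    return counts, valid


def naive_tetramer_stats(seq, z_cap=10.0):
    """(frequencies, z-scores) for all 256 tetramers by direct formula."""
    c4, n4 = naive_word_counts(seq, 4)
    c3, _ = naive_word_counts(seq, 3)
    c2, _ = naive_word_counts(seq, 2)
    freqs = {}
    zs = {}
    for w in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
        o_w = c4.get(w, 0)
        freqs[w] = o_w / n4 if n4 else 0.0
        o_left = c3.get(w[:3], 0)
        o_right = c3.get(w[1:], 0)
        o_mid = c2.get(w[1:3], 0)
        if o_mid == 0:
            zs[w] = 0.0
            continue
        e = o_left * o_right / o_mid
        var = e * (o_mid - o_left) * (o_mid - o_right) / (o_mid ** 2)
        if var <= 0:
            if o_w == e:
                zs[w] = 0.0
            else:
                zs[w] = z_cap if o_w > e else -z_cap
        else:
            zs[w] = (o_w - e) / math.sqrt(var)
    return freqs, zs


def naive_ks_statistic(a, b):
    """sup |ECDF_a - ECDF_b| by evaluating both ECDFs at every data point."""
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def naive_fisher_two_sided(table):
    """Two-sided Fisher exact p by hypergeometric enumeration: the sum of
    probabilities of tables no more probable than the observed one."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def comb(n_, k_):
        return math.comb(n_, k_)

    def prob(a_):
        b_ = row1 - a_
        c_ = col1 - a_
        d_ = row2 - c_
        if min(b_, c_, d_) < 0:
            return 0.0
        return (
            comb(row1, a_) * comb(row2, c_) / comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for a_ in range(0, min(row1, col1) + 1):
        p = prob(a_)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
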