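"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package: plain
scalar loops transcribing the published formulas, so that agreement with
the implementation is a genuine cross-check.
"""

import math


def wc_fst_bruteforce(n_a, alt_a, n_b, alt_b):
    """Weir & Cockerham (1984) theta for one locus, two populations.

    Scalar, component-by-component transcription of the variance components
    a (among populations), b (among individuals within populations) and
    c (within individuals), with Hardy-Weinberg heterozygote proportions.
    ``n_*`` are called allele counts; ``alt_*`` alternate-allele counts.
    """
    r = 2
    sizes = [n_a / 2.0, n_b / 2.0]  # diploid sample sizes
    freqs = [alt_a / n_a, alt_b / n_b]
    hets = [2.0 * p * (1.0 - p) for p in freqs]

    n_bar = sum(sizes) / r
    n_c = (r * n_bar - sum(n**2 for n in sizes) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(sizes, freqs)) / (r * n_bar)
    s_sq = sum(n * (p - p_bar) ** 2 for n, p in zip(sizes, freqs)) / (
        (r - 1) * n_bar
    )
    h_bar = sum(n * h for n, h in zip(sizes, hets)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s_sq
        - (p_bar * (1 - p_bar) - ((r - 1) / r) * s_sq - h_bar / 4.0)
        / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s_sq
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0:
        return math.nan
    return a / denom


def welch_t_textbook(x, y):
    """Welch statistic and Welch-Satterthwaite df from the textbook formulas."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    t = (mx - my) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return t, df


def rank_average(values):
    """Mid-ranks with average ties, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def spearman_bruteforce(x, y):
    """Rank-then-Pearson Spearman correlation."""
    return pearson(rank_average(x), rank_average(y))
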