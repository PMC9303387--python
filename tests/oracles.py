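"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit enumeration, Fractions,
string scanning — and shares no code path with the package implementation.
"""

from fractions import Fraction
from math import comb, log10

RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq):
    return "".join(RC[b] for b in reversed(seq))


def fisher_greater_exact(a, b, c, d):
    """One-sided (greater) Fisher exact p by full hypergeometric enumeration
    with exact rational arithmetic."""
    n_row1, col1, N = a + b, a + c, a + b + c + d
    p = Fraction(0)
    for k in range(a, min(n_row1, col1) + 1):
        if n_row1 - k > N - col1:
            continue
        p += Fraction(comb(col1, k) * comb(N - col1, n_row1 - k), comb(N, n_row1))
    return float(p)


def binom_upper_tail(k, n, q):
    """Exact P(X >= k) for X ~ Binomial(n, q) by term-wise summation."""
    return sum(comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))


def binom_lower_tail(k, n, q):
    return sum(comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(0, k + 1))


def logo_height_oracle(k, n, q):
    if k / n >= q:
        return -log10(binom_upper_tail(k, n, q))
    return log10(binom_lower_tail(k, n, q))


def binom_two_sided(k, n, p=0.5):
    """Two-sided exact binomial p: sum of outcome probabilities <= P(k)."""
    pk = comb(n, k) * p**k * (1 - p) ** (n - k)
    tot = 0.0
    for i in range(n + 1):
        pi = comb(n, i) * p**i * (1 - p) ** (n - i)
        if pi <= pk * (1 + 1e-12):
            tot += pi
    return min(1.0, tot)


def classify_pyrimidine(seq, pos0, ref, alt):
    """(five, base, three, alt) in pyrimidine orientation, by plain strings."""
    ctx = seq[pos0 - 1 : pos0 + 2]
    assert ctx[1] == ref
    if ref in "CT":
        return ctx[0], ref, ctx[2], alt
    r = rc(ctx)
    return r[0], RC[ref], r[2], RC[alt]


def motif_site_positions(seq, five, base, three):
    """All 0-based positions carrying the motif on either strand."""
    comp = RC[base]
    hits = []
    for i in range(len(seq)):
        if seq[i] == base and 0 < i < len(seq) - 1 \
                and seq[i - 1] in IUPAC[five] and seq[i + 1] in IUPAC[three]:
            hits.append(i)
        elif seq[i] == comp and 0 < i < len(seq) - 1 \
                and RC[seq[i + 1]] in IUPAC[five] and RC[seq[i - 1]] in IUPAC[three]:
            hits.append(i)
    return hits


def brute_motif_mutation_counts(records, sequences, five, base, three, alt):
    """(m_motif, m_total) by direct string comparison; records are
    (chrom, pos1, ref, alt) tuples, interior positions only."""
    m_motif = m_total = 0
    for chrom, pos1, ref, a in records:
        seq = sequences[chrom]
        i = pos1 - 1
        if i == 0 or i == len(seq) - 1:
            continue
        f, b, t, al = classify_pyrimidine(seq, i, ref, a)
        if (b, al) != (base, alt):
            continue
        m_total += 1
        if f in IUPAC[five] and t in IUPAC[three]:
            m_motif += 1
    return m_motif, m_total


def brute_context_counts(records, sequences, five, base, three, alt, halfwidth):
    """(c_motif, c_base) by explicit per-window position enumeration."""
    comp = RC[base]
    c_motif = c_base = 0
    for chrom, pos1, ref, a in records:
        seq = sequences[chrom]
        i = pos1 - 1
        if i == 0 or i == len(seq) - 1:
            continue
        f, b, t, al = classify_pyrimidine(seq, i, ref, a)
        if (b, al) != (base, alt):
            continue
        for j in range(i - halfwidth, i + halfwidth + 1):
            if not 0 <= j < len(seq):
                continue
            if seq[j] == base:
                c_base += 1
                if 0 < j < len(seq) - 1 and seq[j - 1] in IUPAC[five] \
                        and seq[j + 1] in IUPAC[three]:
                    c_motif += 1
            elif seq[j] == comp:
                c_base += 1
                if 0 < j < len(seq) - 1 and RC[seq[j + 1]] in IUPAC[five] \
                        and RC[seq[j - 1]] in IUPAC[three]:
                    c_motif += 1
    return c_motif, c_base


def pearson_by_hand(xs, ys):
    """Pearson r from the raw covariance definition."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / (vx * vy) ** 0.5
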