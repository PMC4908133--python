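"""Independent brute-force oracles used by the test suite.

Every function here is written from the defining formula or a naive loop,
deliberately sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb, exp, lgamma, log

import numpy as np


# ---------------------------------------------------------------- reference

def regex_catg_gene_count(sequences: dict[str, str]) -> int:
    """Genes with >= 1 sense CATG site followed by >= 17 bases (regex scan)."""
    pat = re.compile(r"(?=CATG.{17})", re.DOTALL)
    return sum(1 for seq in sequences.values() if pat.search(seq))


def regex_all_tags(sequences: dict[str, str]) -> dict[str, set[str]]:
    """tag 21-mer -> genes carrying it, via regex on both strands."""
    comp = str.maketrans("ACGTN", "TGCAN")
    out: dict[str, set[str]] = {}
    for gene, seq in sequences.items():
        for s in (seq, seq.translate(comp)[::-1]):
            for m in re.finditer(r"(?=(CATG.{17}))", s, re.DOTALL):
                mer = m.group(1)
                if "N" not in mer:
                    out.setdefault(mer, set()).add(gene)
    return out


# ----------------------------------------------------------------------- qc

def naive_filter(counts: dict[str, int], adaptors: set[str]) -> dict[str, int]:
    """One-pass dictionary filter: drop non-ACGT tags, adaptors, then singletons."""
    kept = {}
    for tag, n in counts.items():
        if set(tag) <= set("ACGT") and tag not in adaptors:
            kept[tag] = n
    return {t: n for t, n in kept.items() if n >= 2}


def naive_spectrum(counts: dict[str, int]) -> list[tuple[str, int, int]]:
    rows = []
    for label, test in [(">=2", lambda n: n >= 2), (">5", lambda n: n > 5),
                        (">10", lambda n: n > 10), (">20", lambda n: n > 20),
                        (">50", lambda n: n > 50), (">100", lambda n: n > 100)]:
        sel = [n for n in counts.values() if test(n)]
        rows.append((label, len(sel), sum(sel)))
    return rows


# ------------------------------------------------------------------ mapping

def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_assign(tag: str, ref_tags: dict[str, set[str]]) -> tuple[str, set[str]]:
    """All-pairs Hamming scan: (match_class, gene set at the best class)."""
    exact = ref_tags.get(tag)
    if exact:
        return "exact", set(exact)
    genes: set[str] = set()
    for rt, rgenes in ref_tags.items():
        if hamming(tag, rt) == 1:
            genes |= rgenes
    return ("one_mismatch", genes) if genes else ("unknown", set())


def expected_distinct_subsample(counts: list[int], depth: int) -> float:
    """E[distinct tags] under without-replacement subsampling, via exact
    log-binomial ratios: sum_i 1 - C(T-c_i, d) / C(T, d)."""
    T = sum(counts)

    def logc(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    total = 0.0
    for c in counts:
        if T - c < depth:
            total += 1.0
        else:
            total += 1.0 - exp(logc(T - c, depth) - logc(T, depth))
    return total


# --------------------------------------------------------- Audic - Claverie

def ac_prob_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Direct log-gamma evaluation of
    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))."""
    r = n2 / n1
    return exp(y * log(r) + lgamma(x + y + 1) - lgamma(x + 1) - lgamma(y + 1)
               - (x + y + 1) * log(1 + r))


def ac_two_sided_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p by explicit summation of p(y'|x) with log-sum-exp.

    Both tails are summed term by term (the upper tail up to a cutoff where
    the geometric decay makes the remainder negligible), avoiding the
    cancellation of a complement-based upper tail.
    """
    def log_term(yy):
        r = n2 / n1
        return (yy * log(r) + lgamma(x + yy + 1) - lgamma(x + 1)
                - lgamma(yy + 1) - (x + yy + 1) * log(1 + r))

    logs_lower = [log_term(yy) for yy in range(0, y + 1)]
    m = max(logs_lower)
    lower = exp(m) * sum(exp(v - m) for v in logs_lower)

    logs_upper = []
    yy = y
    while True:
        lt = log_term(yy)
        logs_upper.append(lt)
        # terms decay at least geometrically once past the conditional mean
        if yy > y + 10 and yy > (x + 1) * n2 / n1 and lt < max(logs_upper) - 60:
            break
        yy += 1
    mu = max(logs_upper)
    upper = exp(mu) * sum(exp(v - mu) for v in logs_upper)
    return min(1.0, 2.0 * min(lower, upper))


def stepup_fdr_oracle(pvals: list[float], by: bool = False) -> list[float]:
    """Textbook O(m log m) step-up adjustment (BH; BY multiplies by sum 1/i)."""
    m = len(pvals)
    c = sum(1.0 / i for i in range(1, m + 1)) if by else 1.0
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m * c / rank)
        q[i] = val
        prev = val
    return q


# --------------------------------------------------------------- enrichment

def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact rational upper tail P(X >= k) via integer binomials."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


# --------------------------------------------------------------- clustering

def naive_average_linkage(dist: np.ndarray) -> list[float]:
    """O(n^3) agglomerative average linkage; returns sorted merge heights.

    Ties are broken on the lowest flat index, matching the conventional
    implementation; only heights are compared against the library routine.
    """
    d = dist.astype(float).copy()
    active = {i: [i] for i in range(len(d))}
    heights = []
    while len(active) > 1:
        keys = sorted(active)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                if best is None or d[a, b] < best[0] - 1e-15:
                    best = (d[a, b], a, b)
        h, a, b = best
        heights.append(h)
        na, nb = len(active[a]), len(active[b])
        merged = active.pop(a) + active.pop(b)
        new = max(max(active, default=-1), a, b) + 1
        for other in list(active):
            no = len(active[other])
            avg = sum(dist[i, j] for i in merged for j in active[other]) / (len(merged) * no)
            d = _grow(d, new)
            d[new, other] = d[other, new] = avg
        d = _grow(d, new)
        active[new] = merged
    return sorted(heights)


def _grow(d: np.ndarray, idx: int) -> np.ndarray:
    if idx < len(d):
        return d
    out = np.zeros((idx + 1, idx + 1))
    out[: len(d), : len(d)] = d
    return out
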