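"""Brute-force oracles: explicit loops over sites, samples and haplotype
pairs, written independently of the vectorized implementations."""

import math

import numpy as np

MISSING = -1


def hudson_fst_oracle(dosage, idx_a, idx_b, sites):
    """Ratio-of-sums Hudson F_ST with the n-1 sample-size correction."""
    num_sum = 0.0
    den_sum = 0.0
    for s in sites:
        a = [dosage[s, i] for i in idx_a if dosage[s, i] != MISSING]
        b = [dosage[s, i] for i in idx_b if dosage[s, i] != MISSING]
        n1, n2 = 2 * len(a), 2 * len(b)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = sum(a) / n1, sum(b) / n2
        num_sum += ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum if den_sum > 0 else math.nan


def dxy_oracle(dosage, idx_a, idx_b, sites):
    """Mean between-population difference per comparable site."""
    total = 0.0
    n_cmp = 0
    for s in sites:
        a = [dosage[s, i] for i in idx_a if dosage[s, i] != MISSING]
        b = [dosage[s, i] for i in idx_b if dosage[s, i] != MISSING]
        if not a or not b:
            continue
        p1 = sum(a) / (2 * len(a))
        p2 = sum(b) / (2 * len(b))
        total += p1 * (1 - p2) + p2 * (1 - p1)
        n_cmp += 1
    return total / n_cmp if n_cmp else math.nan


def dxy_self_pairs_oracle(dosage, idx, sites):
    """Mean difference over all ordered haplotype pairs (self-pairs
    included) within one population — equals D_XY of a population with
    itself."""
    total = 0.0
    n_cmp = 0
    for s in sites:
        a = [dosage[s, i] for i in idx if dosage[s, i] != MISSING]
        if not a:
            continue
        n = 2 * len(a)
        j = sum(a)
        haps = [1] * j + [0] * (n - j)
        diffs = sum(1 for x in haps for y in haps if x != y)
        total += diffs / (n * n)
        n_cmp += 1
    return total / n_cmp if n_cmp else math.nan


def tajima_d_oracle(dosage, idx, sites):
    """Tajima's D with pi from an explicit haplotype-pair double loop.

    Complete-case: sites with any missing call in the population are
    excluded.  Unphased dosages determine the multiset of haplotype
    alleles exactly at a biallelic site, so the pair loop is exact.
    """
    n = 2 * len(idx)
    S = 0
    pi = 0.0
    for s in sites:
        alleles = [dosage[s, i] for i in idx]
        if any(a == MISSING for a in alleles):
            continue
        j = sum(alleles)
        if j == 0 or j == n:
            continue
        S += 1
        haps = [1] * j + [0] * (n - j)
        diffs = sum(1 for x in range(n) for y in range(x + 1, n)
                    if haps[x] != haps[y])
        pi += diffs / (n * (n - 1) / 2)
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def pwm_best_score_oracle(seq, matrix):
    """Exhaustive PWM log-odds scan over all offsets and both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    order = "ACGT"
    w = matrix.shape[1]
    best = -math.inf
    for target in (seq, rc):
        for off in range(len(target) - w + 1):
            score = 0.0
            for k in range(w):
                p = max(matrix[order.index(target[off + k]), k], 1e-6)
                score += math.log2(p / 0.25)
            best = max(best, score)
    return best


def random_matrix(rng, n_sites=20, n_samples=8, missing_rate=0.1,
                  invariant_rate=0.3):
    """A random dosage matrix with missingness and invariant sites."""
    dosage = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    invariant = rng.uniform(size=n_sites) < invariant_rate
    dosage[invariant] = 0
    miss = rng.uniform(size=dosage.shape) < missing_rate
    dosage[miss] = MISSING
    return dosage, ~invariant
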