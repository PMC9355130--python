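"""Independent brute-force oracle for the exact Hardy-Weinberg test.

Enumerates, in exact integer arithmetic, the conditional distribution of the
heterozygote count given the allele counts:

    weight(h) = C(n, h) * C(n - h, n_rare_hom) * 2**h

(the multinomial count of genotype configurations times the 2**h phase
factor), and defines the two-sided p-value of an observed h as the exact
rational sum of weights not exceeding weight(h), divided by the total.
No floating point enters until the final conversion.
"""

from fractions import Fraction
from math import comb


def oracle_pvalues(n: int, n_minor: int) -> dict[int, float]:
    """Exact p-value for every feasible heterozygote count."""
    hets = list(range(n_minor % 2, n_minor + 1, 2))
    weights = []
    for h in hets:
        n_rare_hom = (n_minor - h) // 2
        weights.append(comb(n, h) * comb(n - h, n_rare_hom) * (1 << h))
    total = sum(weights)
    order = sorted(range(len(hets)), key=weights.__getitem__)
    prefix = []
    acc = 0
    for k in order:
        acc += weights[k]
        prefix.append(acc)
    # ties: every equal weight contributes; take the last prefix among ties
    pos_of = {}
    for rank, k in enumerate(order):
        pos_of[k] = rank
    out = {}
    for idx, h in enumerate(hets):
        rank = pos_of[idx]
        w = weights[order[rank]]
        while rank + 1 < len(order) and weights[order[rank + 1]] == w:
            rank += 1
        out[h] = float(Fraction(prefix[rank], total))
    return out


def oracle_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    return oracle_pvalues(n, n_minor)[n_het]
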