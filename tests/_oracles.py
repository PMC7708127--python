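"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most literal route possible
(explicit per-site likelihood products, exhaustive string search, full
enumeration) so they stay independent of the package implementations they
check.
"""

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


def _rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def pmd_score_bruteforce(bases, quals, ref, strand, p, c, pi):
    """Literal per-site likelihood product for the damage score.

    Multiplies per-site likelihoods under the damage and null models and
    returns ln(product_damage / product_null).
    """
    if strand == "-":
        bases = _rc(bases)
        ref = _rc(ref)
        quals = list(reversed(quals))
    L = len(bases)
    log_num = 0.0
    log_den = 0.0
    n_sites = 0
    for i in range(L):
        r = ref[i].upper()
        b = bases[i].upper()
        eps = 10.0 ** (-quals[i] / 10.0)
        if r == "C":
            z = i + 1
            damaged, undamaged = "T", "C"
        elif r == "G":
            z = L - i
            damaged, undamaged = "A", "G"
        else:
            continue
        d = min(1.0, max(0.0, p * (1.0 - p) ** (z - 1) + c))
        for m, accumulate in ((d + pi - d * pi, "num"), (pi, "den")):
            if b == damaged:
                lik = m * (1.0 - eps) + (1.0 - m) * eps / 3.0
            elif b == undamaged:
                lik = (1.0 - m) * (1.0 - eps) + m * eps / 3.0
            else:
                lik = None
            if lik is not None:
                if accumulate == "num":
                    log_num += math.log(lik)
                else:
                    log_den += math.log(lik)
        if b in (damaged, undamaged):
            n_sites += 1
    return log_num - log_den, n_sites


def find_all_placements(destination, kmer):
    """Every forward-strand (chrom, pos) where kmer or its reverse
    complement occurs, by exhaustive string scan."""
    hits = set()
    for needle in {kmer, _rc(kmer)}:
        if "N" in needle:
            continue
        for chrom, seq in destination.items():
            start = 0
            while True:
                pos = seq.find(needle, start)
                if pos == -1:
                    break
                hits.add((chrom, pos))
                start = pos + 1
    return sorted(hits)


def conserved_union_bruteforce(source, destination, k):
    """Slide every k-mer of source over destination; positions covered by
    uniquely placed k-mers, merged into intervals."""
    covered = {}
    for _chrom, seq in source.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            placements = find_all_placements(destination, kmer)
            if len(placements) == 1:
                chrom, pos = placements[0]
                covered.setdefault(chrom, set()).update(range(pos, pos + k))
    intervals = []
    for chrom in sorted(covered):
        positions = sorted(covered[chrom])
        start = prev = positions[0]
        for pos in positions[1:]:
            if pos != prev + 1:
                intervals.append((chrom, start, prev + 1))
                start = pos
            prev = pos
        intervals.append((chrom, start, prev + 1))
    return intervals


def wilcoxon_enumeration(x, y, alternative="two_sided"):
    """Exact rank-sum p-value by enumerating every assignment of the
    pooled ranks to the first sample (distinct values only)."""
    n1 = len(x)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks_of[v] for v in x) - n1 * (n1 + 1) / 2
    us = [
        sum(combo) - n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    total = len(us)
    cdf = sum(1 for u in us if u <= u_obs) / total
    sf = sum(1 for u in us if u >= u_obs) / total
    if alternative == "less":
        return cdf
    if alternative == "greater":
        return sf
    return min(1.0, 2.0 * min(cdf, sf))
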