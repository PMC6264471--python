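"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or accumulation,
staying deliberately independent of the library implementation it checks.
"""

from functools import lru_cache


def residue_accumulation(peptides, length):
    """Per-residue intensity totals by direct per-peptide accumulation.

    ``peptides`` is an iterable of (start, stop, intensity), 1-based
    inclusive.
    """
    values = [0.0] * length
    for start, stop, intensity in peptides:
        for i in range(start, stop + 1):
            values[i - 1] += intensity
    return values


def windowed_weighted_mean(series, weights):
    """Sliding weighted mean with edge renormalization, one loop per
    position."""
    n = len(series)
    half = len(weights) // 2
    out = []
    for i in range(n):
        num = 0.0
        den = 0.0
        for k, w in enumerate(weights):
            j = i - half + k
            if 0 <= j < n:
                num += w * series[j]
                den += w
        out.append(num / den)
    return out


def max_alignment_identities(a, b):
    """Maximum number of identical aligned pairs over all global
    alignments (identity scoring: match 1, mismatch/gap 0), by exhaustive
    recursion over alignment moves."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(a) or j == len(b):
            return 0
        options = [
            best(i + 1, j + 1) + (1 if a[i] == b[j] else 0),
            best(i + 1, j),
            best(i, j + 1),
        ]
        return max(options)

    result = best(0, 0)
    best.cache_clear()
    return result


def enumerate_affine_alignment_score(a, b, match_scores, open_gap, extend_gap):
    """Best global alignment score under affine gaps by exhaustive
    enumeration of move sequences (no dynamic-programming sharing of the
    gap state beyond memoization on it).

    ``match_scores(x, y)`` returns the substitution score.  The first
    residue of a gap costs ``open_gap``, every further one ``extend_gap``.
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 diagonal/start, 1 gap in b (a consumed), 2 gap in a
        if i == len(a) and j == len(b):
            return 0.0
        candidates = []
        if i < len(a) and j < len(b):
            candidates.append(
                match_scores(a[i], b[j]) + best(i + 1, j + 1, 0)
            )
        if i < len(a):
            cost = extend_gap if state == 1 else open_gap
            candidates.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = extend_gap if state == 2 else open_gap
            candidates.append(cost + best(i, j + 1, 2))
        return max(candidates)

    result = best(0, 0, 0)
    best.cache_clear()
    return result
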