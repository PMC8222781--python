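"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive results from first principles (exhaustive
enumeration) and share no code with the package internals.
"""

from __future__ import annotations


def valid_segment(scores, i, j, threshold, max_gap):
    """Is [i, j] (0-based inclusive) a valid IDR segment ignoring min_len?

    Valid means: endpoints above threshold and every maximal interior run
    of sub-threshold residues has length <= max_gap.
    """
    if scores[i] < threshold or scores[j] < threshold:
        return False
    run = 0
    for k in range(i, j + 1):
        if scores[k] < threshold:
            run += 1
            if run > max_gap:
                return False
        else:
            run = 0
    return True


def brute_force_segments(scores, threshold, min_len, max_gap):
    """All maximal valid segments of length >= min_len, as 1-based
    inclusive (start, end) pairs, by exhaustive interval enumeration."""
    n = len(scores)
    valid = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if j - i + 1 >= min_len and valid_segment(scores, i, j, threshold, max_gap)
    ]
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any(
            (a <= i and j <= b) and (a, b) != (i, j) for (a, b) in valid
        )
    ]
    return sorted((i + 1, j + 1) for i, j in maximal)


def brute_force_kmers(region_seqs, k):
    """Per-region sliding-window k-mer counts, pooled, by direct enumeration."""
    counts = {}
    for seq in region_seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def jaccard(intervals_a, intervals_b):
    """Jaccard overlap of two interval sets (1-based inclusive) as residue sets."""
    set_a = {p for s, e in intervals_a for p in range(s, e + 1)}
    set_b = {p for s, e in intervals_b for p in range(s, e + 1)}
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)
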