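"""Brute-force reference implementations of the repeat definitions.

Independent of the package's scanners: these enumerate every fixed-size
window against the literal definitions (h copies of one letter; d copies of
a two-distinct-letter unit) and merge overlapping findings.  Any run longer
than the threshold is the union of its overlapping threshold-length windows,
so the merged output equals the set of maximal repetitive intervals.
"""


def merge_overlapping(intervals):
    """Merge strictly overlapping intervals; touching intervals stay separate."""
    out = []
    for a, b in sorted(intervals):
        if out and a < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def brute_homopolymers(s, h):
    s = s.upper()
    hits = [
        (i, i + h)
        for i in range(len(s) - h + 1)
        if s[i : i + h] == s[i] * h
    ]
    return merge_overlapping(hits)


def brute_dinucleotides(s, d):
    s = s.upper()
    hits = []
    for i in range(len(s) - 2 * d + 1):
        unit = s[i : i + 2]
        if unit[0] != unit[1] and s[i : i + 2 * d] == unit * d:
            hits.append((i, i + 2 * d))
    return merge_overlapping(hits)


def brute_mask(s, h, d, delta):
    ivs = brute_homopolymers(s, h) + brute_dinucleotides(s, d)
    return [
        any(a - delta <= j <= b - 1 + delta for a, b in ivs)
        for j in range(len(s))
    ]
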