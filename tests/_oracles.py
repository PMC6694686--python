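"""Independent brute-force oracles used by the test suite.

These deliberately share no code (and no lookup tables) with the package:
IUPAC expansion, complementation and window enumeration are re-declared
from first principles so that agreement is evidence, not tautology.
"""

from itertools import combinations

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_rc_motif(motif):
    pairs = {
        "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
        "K": "M", "M": "K", "S": "S", "W": "W", "B": "V", "V": "B",
        "D": "H", "H": "D", "N": "N",
    }
    return "".join(pairs[c] for c in motif[::-1])


def oracle_window_match(motif, window):
    if len(window) != len(motif):
        return False
    for code, base in zip(motif, window.upper()):
        if base not in ORACLE_IUPAC[code]:
            return False
    return True


def oracle_scan(seq, motif):
    """All (start, strand) PAM occurrences by naive window enumeration."""
    seq = seq.upper()
    L = len(motif)
    rc = oracle_rc_motif(motif)
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if oracle_window_match(motif, window):
            hits.append((i, "+"))
        if oracle_window_match(rc, window):
            hits.append((i, "-"))
    return sorted(hits)


def oracle_pairs(positions_haps, max_distance):
    """Brute-force same-haplotype pair enumeration on (pos, hap) tuples."""
    out = set()
    for (p1, h1), (p2, h2) in combinations(positions_haps, 2):
        if h1 == h2 and abs(p2 - p1) < max_distance:
            out.add((min(p1, p2), max(p1, p2)))
    return out


def oracle_max_coverage(neighborhoods, k):
    """Best coverage over all <=k subsets of pair ids; returns the count."""
    pairs = sorted(neighborhoods)
    best = 0
    m = min(k, len(pairs))
    for subset in combinations(pairs, m):
        covered = set()
        for p in subset:
            covered |= set(neighborhoods[p])
        best = max(best, len(covered))
    return best
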