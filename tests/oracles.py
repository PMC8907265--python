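"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from first principles on top of
Biopython's genetic code, sharing no code with the package: explicit
enumeration of single-nucleotide neighbours for site counts and explicit
enumeration of all mutational pathways for pairwise difference counts.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa_of(codon) == "*"


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """(s, n) for a sense codon by explicit neighbour enumeration."""
    aa = aa_of(codon)
    s = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]
        ]
        sense = [c for c in neighbours if not is_stop(c)]
        if sense:
            s += sum(aa_of(c) == aa for c in sense) / len(sense)
    return s, 3.0 - s


def oracle_codon_pair(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over stop-free minimal pathways, enumerated explicitly."""
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(diff):
        path = [codon_a]
        for pos in order:
            cur = path[-1]
            path.append(cur[:pos] + codon_b[pos] + cur[pos + 1 :])
        all_paths.append(path)
    clean = [p for p in all_paths if not any(is_stop(c) for c in p[1:-1])]
    used = clean if clean else all_paths
    sd = nd = 0.0
    for path in used:
        for before, after in zip(path, path[1:]):
            if is_stop(before) or is_stop(after):
                nd += 1
            elif aa_of(before) == aa_of(after):
                sd += 1
            else:
                nd += 1
    return sd / len(used), nd / len(used)


def oracle_ng86(row_a: str, row_b: str) -> tuple[float, float]:
    """(Ka, Ks) by the brute-force route; NaN where undefined."""
    assert len(row_a) == len(row_b) and len(row_a) % 3 == 0
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(row_a), 3):
        ca, cb = row_a[k : k + 3].upper(), row_b[k : k + 3].upper()
        if set(ca) <= set(BASES) and set(cb) <= set(BASES) and not is_stop(ca) and not is_stop(cb):
            n_codons += 1
            s_a += oracle_site_counts(ca)[0]
            s_b += oracle_site_counts(cb)[0]
            d = oracle_codon_pair(ca, cb)
            sd += d[0]
            nd += d[1]
    if n_codons == 0:
        return math.nan, math.nan
    S = (s_a + s_b) / 2
    N = 3 * n_codons - S
    out = []
    for d, sites in ((nd, N), (sd, S)):
        p = d / sites
        out.append(math.nan if p >= 0.75 else -0.75 * math.log(1 - p / 0.75) if p > 0 else 0.0)
    return out[0], out[1]


def oracle_windows(length: int) -> list[tuple[int, int]]:
    """All (start, start+98) spans with start in 1, 10, 19, ... fitting length."""
    return [
        (s, s + 98) for s in range(1, length + 1, 9) if s + 98 <= length
    ]
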