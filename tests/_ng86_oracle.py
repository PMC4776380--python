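"""Brute-force oracle for Nei-Gojobori counting, independent of the package.

Everything here is written from the method's definition with exact
rational arithmetic (fractions), explicit path lists and Biopython's
translation table -- deliberately sharing no code with
``effectorkit.selection``.
"""

from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def oracle_sites(codon: str) -> tuple[Fraction, Fraction]:
    """Expected (synonymous, nonsynonymous) sites; stop targets are nonsynonymous."""
    syn = Fraction(0)
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if not is_stop(mutant) and aa(mutant) == aa(codon):
                syn += Fraction(1, 3)
    return syn, Fraction(3) - syn


def _all_paths(a: str, b: str) -> list[list[str]]:
    """Every minimal path a -> b as an explicit list of codons visited."""
    if a == b:
        return [[a]]
    paths = []
    for pos in range(3):
        if a[pos] != b[pos]:
            step = a[:pos] + b[pos] + a[pos + 1:]
            for tail in _all_paths(step, b):
                paths.append([a] + tail)
    return paths


def oracle_differences(a: str, b: str) -> tuple[Fraction, Fraction]:
    """Equal-weight pathway average of (syn, nonsyn) differences.

    Paths visiting a stop codon at an intermediate position are
    excluded; if none survive, all paths are used.
    """
    if a == b:
        return Fraction(0), Fraction(0)
    paths = _all_paths(a, b)
    ok = [p for p in paths if not any(is_stop(c) for c in p[1:-1])]
    if not ok:
        ok = paths
    syn = nonsyn = Fraction(0)
    for p in ok:
        for x, y in zip(p, p[1:]):
            if aa(x) == aa(y):
                syn += 1
            else:
                nonsyn += 1
    return syn / len(ok), nonsyn / len(ok)


def oracle_counts(seq_a: str, seq_b: str) -> tuple[Fraction, Fraction, Fraction, Fraction]:
    """(S, N, Sd, Nd) over a pair of gap-free CDS of equal length."""
    S = N = Sd = Nd = Fraction(0)
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd
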