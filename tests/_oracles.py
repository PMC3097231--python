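"""Independent brute-force oracles used to check the package's optimised paths.

These are deliberately naive, self-contained implementations written straight
from the method definitions: the window scanner enumerates every window with
its own IUPAC table, and the codon-pair counter enumerates neighbours and
mutational pathways with its own genetic code (taken from Bio.Seq.translate,
not from the package).  They share no code with ``xenoscan``.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def window_mismatches(window: str, pattern: str) -> int:
    m = 0
    for w, p in zip(window, pattern):
        if p == "N":
            continue
        if w not in IUPAC_SETS[p]:
            m += 1
    return m


def brute_force_scan(seq: str, pattern: str, budget: int, both_strands: bool = True):
    """Set of (start, strand, mismatches) found by testing every window."""
    L = len(pattern)
    out = set()
    for start in range(len(seq) - L + 1):
        w = seq[start : start + L]
        m = window_mismatches(w, pattern)
        if m <= budget:
            out.add((start, "+", m))
        if both_strands:
            m = window_mismatches(_rc(w), pattern)
            if m <= budget:
                out.add((start, "-", m))
    return out


_TRANSLATE_CACHE: dict[str, str] = {}


def translate(codon: str) -> str:
    if codon not in _TRANSLATE_CACHE:
        _TRANSLATE_CACHE[codon] = str(Seq(codon).translate())  # '*' for stops
    return _TRANSLATE_CACHE[codon]


STOPS = {c for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
         if translate(c) == "*"}


def codon_sites(codon: str) -> tuple[float, float]:
    """(S, N) site counts of one codon; nonsense changes excluded from fractions."""
    aa = translate(codon)
    s = 0.0
    for i in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in STOPS:
                continue
            valid += 1
            if translate(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over minimal stop-free pathways (all pathways if none)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def path(order, allow_stops):
        sd = nd = 0
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS and not allow_stops:
                return None
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [p for p in (path(o, False) for o in permutations(diff)) if p is not None]
    if not paths:
        paths = [path(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) for two aligned coding sequences, codon by codon."""
    N = S = Nd = Sd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if set(c1 + c2) - set("ACGT") or c1 in STOPS or c2 in STOPS:
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = codon_pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


def random_orf(rng, n_codons: int) -> str:
    """Uniform-random stop-free coding sequence."""
    sense = sorted(
        c for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
        if c not in STOPS
    )
    return "".join(sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons))


def neutral_pair(rng, n_codons: int, n_subs: int) -> tuple[str, str]:
    """An ORF and a copy with ``n_subs`` uniform substitutions (stop-free)."""
    orf = random_orf(rng, n_codons)
    mutant = list(orf)
    positions = list(rng.permutation(len(orf)))
    placed = 0
    for pos in positions:
        if placed == n_subs:
            break
        bases = [b for b in "ACGT" if b != mutant[pos]]
        rng.shuffle(bases)
        for b in bases:
            trial = mutant.copy()
            trial[pos] = b
            ci = pos // 3
            if "".join(trial[3 * ci : 3 * ci + 3]) in STOPS:
                continue
            mutant = trial
            placed += 1
            break
    if placed < n_subs:
        raise RuntimeError("could not place all substitutions")
    return orf, "".join(mutant)
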