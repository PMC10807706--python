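"""Brute-force NG86 oracle shared by the acceptance suite.

Deliberately naive and independent of polykit.kaks: amino acids come from
Bio.Seq translation, synonymous sites from explicit enumeration of all nine
single-base changes per codon, and differences from explicit enumeration of
every mutational pathway ordering.
"""

import itertools

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon):
    from Bio.Seq import Seq

    return "*" if codon in STOPS else str(Seq(codon).translate())


def syn_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if aa(alt) != "*" and aa(alt) == aa(codon):
                syn += 1
        s += syn / 3.0
    return s


def pathway_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    valid, blocked = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                stop = True
            if aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop else valid).append((sd, nd))
    use = valid or blocked
    if not use:
        return 0.0, 0.0
    return (sum(u[0] for u in use) / len(use), sum(u[1] for u in use) / len(use))


def oracle_counts(cds1, cds2):
    S = Nd = Sd = 0.0
    codons = 0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i:i + 3], cds2[i:i + 3]
        codons += 1
        S += (syn_sites(c1) + syn_sites(c2)) / 2
        sd, nd = pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd
    return 3 * codons - S, S, Nd, Sd


def random_cds_pair(rng, n_codons, rate):
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in STOPS]
    c1 = [sense[rng.integers(0, len(sense))] for _ in range(n_codons)]

    def mutate_codon(codon):
        while True:
            out = list(codon)
            for j in range(3):
                if rng.random() < rate:
                    out[j] = "ACGT"[("ACGT".index(out[j]) + rng.integers(1, 4)) % 4]
            cand = "".join(out)
            if cand not in STOPS:
                return cand

    return "".join(c1), "".join(mutate_codon(c) for c in c1)
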