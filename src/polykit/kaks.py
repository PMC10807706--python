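"""Nei-Gojobori (NG86) Ka/Ks and paired subgenome-dominance comparison.

Synonymous/nonsynonymous site counts follow the classic NG86 conventions:
each codon position contributes the fraction of its three possible
single-base changes that are synonymous (changes creating stop codons count
as nonsynonymous sites); codons differing at several positions are averaged
over all minimal mutational pathways with equal weights, pathways passing
through stop codons excluded.  pN and pS are Jukes-Cantor corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    if codon in _STOPS:
        return "*"
    return unambiguous_dna_by_id[1].forward_table[codon]


_AA = {c: _aa(c) for c in _CODONS}


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3)."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _AA[alt] != "*" and _AA[alt] == _AA[codon]:
                syn += 1
        s += syn / 3
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over all minimal mutational pathways; pathways through stop
    codons are excluded (all pathways used when every one is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
            if _AA.get(cur, "*") == _AA.get(nxt, "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else results).append((sd, nd))
    use = results if results else blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log(1 - 4 * p / 3))


@dataclass
class KaKsRecord:
    """NG86 site/difference counts and corrected rates for one CDS pair."""

    pair_id: str
    subgenome: str
    codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    ratio: float  # NaN when Ks == 0 or a rate is saturated
    saturated: bool = False


def ng86_kaks(cds_1: str, cds_2: str, pair_id: str = "",
              subgenome: str = "") -> KaKsRecord:
    """NG86 Ka/Ks for an ungapped pair of equal-length coding sequences.

    Codons containing non-ACGT characters in either sequence are skipped
    pairwise; internal stop codons are rejected.
    """
    cds_1, cds_2 = cds_1.upper(), cds_2.upper()
    if len(cds_1) != len(cds_2):
        raise ValueError("CDS lengths differ (pre-aligned ungapped input required)")
    if len(cds_1) % 3:
        raise ValueError("CDS length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(cds_1), 3):
        c1, c2 = cds_1[i : i + 3], cds_2[i : i + 3]
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(f"internal stop codon at position {i}")
        codons += 1
        S += (synonymous_sites(c1) + synonymous_sites(c2)) / 2
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    N = 3 * codons - S
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    Ka, Ks = _jc(pN), _jc(pS)
    saturated = bool(np.isnan(Ka) or np.isnan(Ks))
    if saturated or Ks == 0 or np.isnan(Ks):
        ratio = float("nan")
    else:
        ratio = Ka / Ks
    return KaKsRecord(pair_id=pair_id, subgenome=subgenome, codons=codons,
                      N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, Ka=Ka, Ks=Ks,
                      ratio=ratio, saturated=saturated)


def kaks_table(cds_by_gene: dict, outgroup_cds: dict, pairs: pd.DataFrame,
               subgenomes: list[str]) -> pd.DataFrame:
    """Ka/Ks of every subgenome gene copy against its outgroup anchor.

    ``pairs`` is the homeolog pairing table (anchor + per-subgenome gene
    ids via ``gene_a``/``gene_x``); each copy is dated against the
    outgroup CDS of the same anchor, so each anchor yields one Ka/Ks value
    per subgenome - the paired samples the dominance comparison needs.
    """
    rows = []
    seen = set()
    for r in pairs.itertuples():
        anchor = r.anchor
        for gid, sub in ((r.gene_a, subgenomes[0]), (r.gene_x, r.x)):
            if (anchor, sub) in seen or gid not in cds_by_gene:
                continue
            if anchor not in outgroup_cds:
                continue
            seen.add((anchor, sub))
            rec = ng86_kaks(cds_by_gene[gid], outgroup_cds[anchor],
                            pair_id=anchor, subgenome=sub)
            rows.append(vars(rec))
    return pd.DataFrame(rows)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray):
    """Paired Wilcoxon signed-rank test; zero differences dropped, exact
    null for n <= 25, normal approximation with continuity correction
    beyond.  All-zero differences return (0, 1.0, 0) by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    nz = a != b
    n_eff = int(nz.sum())
    if n_eff == 0:
        return 0.0, 1.0, 0
    method = "exact" if n_eff <= 25 else "approx"
    res = stats.wilcoxon(a[nz], b[nz], zero_method="wilcox",
                         correction=True, method=method)
    return float(res.statistic), float(res.pvalue), n_eff


def compare_subgenomes(records: pd.DataFrame, reference: str | None = None):
    """Per-subgenome median Ka/Ks and paired Wilcoxon vs the reference.

    Records with undefined ratios are excluded (their count reported);
    pairing uses the shared anchor ``pair_id``.  Fewer than 6 usable pairs
    still runs (the exact test) with a warning column.
    """
    subs = sorted(records["subgenome"].unique())
    if reference is None:
        reference = subs[0]
    med_rows = []
    for sub in subs:
        grp = records[records["subgenome"] == sub]
        usable = grp[np.isfinite(grp["ratio"])]
        med_rows.append({
            "subgenome": sub, "n": len(grp), "n_usable": len(usable),
            "n_na_ratio": len(grp) - len(usable),
            "median_ratio": float(usable["ratio"].median()) if len(usable) else np.nan,
            "median_Ka": float(usable["Ka"].median()) if len(usable) else np.nan,
            "median_Ks": float(usable["Ks"].median()) if len(usable) else np.nan,
        })
    medians = pd.DataFrame(med_rows)
    ref_map = records[records["subgenome"] == reference].set_index("pair_id")["ratio"]
    test_rows = []
    for sub in subs:
        if sub == reference:
            continue
        x_map = records[records["subgenome"] == sub].set_index("pair_id")["ratio"]
        common = ref_map.index.intersection(x_map.index)
        a = ref_map.loc[common].to_numpy()
        b = x_map.loc[common].to_numpy()
        stat, p, n_eff = paired_wilcoxon(a, b)
        test_rows.append({
            "comparison": f"{reference}_vs_{sub}", "n_pairs": len(common),
            "n_effective": n_eff, "statistic": stat, "p_value": p,
            "low_n_warning": n_eff < 6,
        })
    return medians, pd.DataFrame(test_rows)
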