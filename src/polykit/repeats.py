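"""Telomere arrays, centromeric tandem monomers, TE composition,
gene-TE distances and LTR insertion-time dating.

Insertion times use twin-LTR divergence: the two LTRs of a retrotransposon
are identical at insertion, so with raw mismatch proportion ``p`` the
Jukes-Cantor distance ``K = -(3/4) ln(1 - 4p/3)`` divided by twice the
substitution rate ``mu`` (substitutions/site/year) dates the insertion,
``T = K / (2 mu)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Genome, FeatureSet, GenomicInterval
from ._seq import encode, revcomp

DEFAULT_MU = 1.3e-8  # substitutions/site/year, a widely used plant LTR clock


# ---------------------------------------------------------------------------
# telomeres


def _scan_end(codes: np.ndarray, motif_codes: np.ndarray, min_copies: int,
              max_mismatch_frac: float):
    """Maximal runs of tandem motif copies (per-copy mismatch fraction
    bounded).  Returns list of (start_offset, n_copies)."""
    L = len(motif_codes)
    n = codes.size - L + 1
    if n <= 0:
        return []
    sw = np.lib.stride_tricks.sliding_window_view(codes, L)
    mism = (sw != motif_codes).sum(axis=1)
    ok = mism / L <= max_mismatch_frac
    run = np.zeros(n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        if ok[i]:
            run[i] = 1 + (run[i + L] if i + L < n else 0)
    calls = []
    for i in range(n):
        if run[i] >= min_copies and (i - L < 0 or not ok[i - L]):
            calls.append((i, int(run[i])))
    return calls


def find_telomeres(genome: Genome, motif: str = "TTTAGGG", min_copies: int = 10,
                   end_window: int = 10_000,
                   max_mismatch_frac: float = 1 / 7) -> pd.DataFrame:
    """Detect tandem telomere-motif arrays near chromosome termini.

    The motif is searched within ``end_window`` of the 5' end, its reverse
    complement within ``end_window`` of the 3' end.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if end_window < len(motif) * min_copies:
        raise ValueError("end_window shorter than min_copies motif copies")
    m5 = encode(motif)
    m3 = encode(revcomp(motif))
    rows = []
    for chrom in genome.names:
        seq = genome[chrom]
        L = len(seq)
        w = min(end_window, L)
        head = encode(seq[:w])
        for off, copies in _scan_end(head, m5, min_copies, max_mismatch_frac):
            rows.append({"chrom": chrom, "end": "5p", "start": off,
                         "stop": off + copies * len(motif), "copies": copies,
                         "motif": motif})
        tail_off = L - w
        tail = encode(seq[tail_off:])
        for off, copies in _scan_end(tail, m3, min_copies, max_mismatch_frac):
            rows.append({"chrom": chrom, "end": "3p", "start": tail_off + off,
                         "stop": tail_off + off + copies * len(motif),
                         "copies": copies, "motif": revcomp(motif)})
    return pd.DataFrame(rows, columns=["chrom", "end", "start", "stop",
                                       "copies", "motif"])


# ---------------------------------------------------------------------------
# tandem monomer (centromere satellite) detection


@dataclass
class MonomerCall:
    start: int
    end: int
    period: int
    copies: float
    consensus: str
    identity: float


def detect_tandem_monomer(sequence: str, period_min: int = 50,
                          period_max: int = 200, min_array_len: int = 2000,
                          match_threshold: float = 0.8,
                          period_tol: float = 0.02) -> list[MonomerCall]:
    """Detect tandem arrays by self-match periodicity.

    For each candidate region the period ``p*`` maximising the fraction of
    positions with ``seq[i] == seq[i+p]`` is chosen; regions where that
    fraction stays >= ``match_threshold`` are reported.  When several
    periods are within ``period_tol`` of the best fraction (e.g. a period
    and its multiples), the smallest is reported.
    """
    if period_min < 2:
        raise ValueError("period_min must be >= 2")
    codes = encode(sequence)
    L = codes.size
    if L < min_array_len:
        return []
    win = min(min_array_len, 2000)
    periods = range(period_min, min(period_max, L - 1) + 1)
    mask = np.zeros(L, dtype=bool)
    for p in periods:
        m = (codes[: L - p] == codes[p:]) & (codes[: L - p] <= 3)
        if m.size < win:
            continue
        cs = np.concatenate([[0], np.cumsum(m)])
        frac = (cs[win:] - cs[:-win]) / win
        good = np.nonzero(frac >= match_threshold)[0]
        for i in good:
            mask[i : i + win] = True
    # label contiguous candidate regions
    calls = []
    i = 0
    while i < L:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < L and mask[j]:
            j += 1
        if j - i >= min_array_len:
            call = _characterise_region(codes, i, j, period_min, period_max,
                                        match_threshold, period_tol)
            if call is not None:
                calls.append(call)
        i = j
    return calls


def _characterise_region(codes, a, b, period_min, period_max,
                         match_threshold, period_tol):
    region = codes[a:b]
    n = region.size
    fracs = {}
    for p in range(period_min, min(period_max, n - 1) + 1):
        m = region[: n - p] == region[p:]
        if m.size:
            fracs[p] = float(m.mean())
    if not fracs:
        return None
    best = max(fracs.values())
    if best < match_threshold:
        return None
    p_star = min(p for p, f in fracs.items()
                 if f >= match_threshold and f >= best - period_tol)
    # greedy period-wise extension: the windowed candidate mask cannot reach
    # the last partial window of an array
    L = codes.size
    while b + p_star <= L and (codes[b : b + p_star] == codes[b - p_star : b]).mean() >= match_threshold:
        b += p_star
    while a - p_star >= 0 and (codes[a - p_star : a] == codes[a : a + p_star]).mean() >= match_threshold:
        a -= p_star
    region = codes[a:b]
    n = region.size
    n_copies = n // p_star
    if n_copies < 2:
        return None

    def _consensus(stack):
        cons = np.zeros(stack.shape[1], dtype=np.uint8)
        for col in range(stack.shape[1]):
            vals, cnts = np.unique(stack[:, col], return_counts=True)
            cons[col] = vals[np.argmax(cnts)]
        return cons

    stack = region[: n_copies * p_star].reshape(n_copies, p_star)
    consensus = _consensus(stack)
    # trim flanking pseudo-copies picked up by the windowed candidate mask
    per_copy = (stack == consensus).mean(axis=1)
    good = per_copy >= match_threshold
    first, last = 0, n_copies - 1
    while first <= last and not good[first]:
        first += 1
    while last >= first and not good[last]:
        last -= 1
    if last - first + 1 < 2:
        return None
    stack = stack[first : last + 1]
    consensus = _consensus(stack)
    identity = float((stack == consensus).mean())
    start = a + first * p_star
    end = a + (last + 1) * p_star
    from ._seq import decode

    return MonomerCall(start=start, end=end, period=p_star,
                       copies=(end - start) / p_star,
                       consensus=decode(consensus), identity=identity)


def find_monomers(genome: Genome, period_min: int = 50, period_max: int = 200,
                  min_array_len: int = 2000,
                  match_threshold: float = 0.8) -> pd.DataFrame:
    """Run the tandem-monomer detector over every chromosome."""
    rows = []
    for chrom in genome.names:
        for call in detect_tandem_monomer(genome[chrom], period_min, period_max,
                                          min_array_len, match_threshold):
            rows.append({"chrom": chrom, "start": call.start, "stop": call.end,
                         "period": call.period, "copies": call.copies,
                         "identity": call.identity, "consensus": call.consensus})
    return pd.DataFrame(rows, columns=["chrom", "start", "stop", "period",
                                       "copies", "identity", "consensus"])


# ---------------------------------------------------------------------------
# TE composition


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent [start, end) intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def te_composition(tes: FeatureSet, genome: Genome) -> pd.DataFrame:
    """Per-subgenome masked fraction, total and per TE class.

    Overlapping intervals are merged per class (and overall) before
    summing, so nested/overlapping annotations are not double counted.
    Chromosomes without a parsed subgenome label group under "unassigned".
    """
    sub_len: dict[str, int] = {}
    chrom_sub = {}
    for name in genome.names:
        sub = genome.subgenome(name) or "unassigned"
        chrom_sub[name] = sub
        sub_len[sub] = sub_len.get(sub, 0) + genome.length(name)
    df = tes.df
    classes = sorted(c for c in df["classification"].unique() if c)
    rows = []
    for sub in sorted(sub_len):
        chroms = [c for c, s in chrom_sub.items() if s == sub]
        sel = df[df["chrom"].isin(chroms)]
        row = {"subgenome": sub, "length": sub_len[sub]}
        all_merged = 0
        for chrom in chroms:
            per_chrom = sel[sel["chrom"] == chrom]
            all_merged += sum(e - s for s, e in
                              merge_intervals(zip(per_chrom["start"], per_chrom["end"])))
        row["total_fraction"] = all_merged / sub_len[sub]
        for cls in classes:
            bases = 0
            for chrom in chroms:
                per = sel[(sel["chrom"] == chrom) & (sel["classification"] == cls)]
                bases += sum(e - s for s, e in
                             merge_intervals(zip(per["start"], per["end"])))
            row[cls] = bases / sub_len[sub]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-TE distance and intragenic/intergenic labels


def gene_te_distance(genes: FeatureSet, tes: FeatureSet,
                     cutoff: int = 500) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance from every gene to its closest TE (0 when overlapping).

    Returns (per-gene table, per-subgenome summary with the fraction of
    genes within ``cutoff`` bases).  Genes on chromosomes without TEs get
    an undefined distance and are excluded from the fraction.
    """
    te_by_chrom = {}
    for chrom, sub in tes.df.groupby("chrom"):
        merged = merge_intervals(zip(sub["start"], sub["end"]))
        te_by_chrom[chrom] = (
            np.array([s for s, _ in merged]), np.array([e for _, e in merged]),
        )
    rows = []
    for r in genes.df.itertuples():
        if r.chrom not in te_by_chrom:
            dist = np.nan
        else:
            starts, ends = te_by_chrom[r.chrom]
            i = np.searchsorted(starts, r.end)
            dist_after = starts[i] - r.end if i < starts.size else np.inf
            overlap = i > 0 and ends[i - 1] > r.start
            dist_before = r.start - ends[i - 1] if i > 0 else np.inf
            dist = 0 if overlap else float(min(dist_before, dist_after))
            if not np.isfinite(dist):
                dist = np.nan
        import re as _re

        m = _re.match(r"chr_(\d+)([A-Z])$", r.chrom)
        rows.append({"gene_id": r.id, "chrom": r.chrom,
                     "subgenome": m.group(2) if m else "unassigned",
                     "distance": dist})
    per_gene = pd.DataFrame(rows)
    per_gene["within_cutoff"] = per_gene["distance"] <= cutoff
    summ = []
    for sub, g in per_gene.groupby("subgenome"):
        defined = g[g["distance"].notna()]
        summ.append({
            "subgenome": sub, "n_genes": len(g), "n_defined": len(defined),
            "n_undefined": int(g["distance"].isna().sum()),
            "fraction_within_cutoff": (
                float(defined["within_cutoff"].mean()) if len(defined) else np.nan
            ),
            "cutoff": cutoff,
        })
    return per_gene, pd.DataFrame(summ)


def classify_te_position(genes: FeatureSet, tes: FeatureSet) -> pd.DataFrame:
    """Label each TE intragenic (overlaps any gene body by >= 1 base) or
    intergenic."""
    gene_by_chrom = {}
    for chrom, sub in genes.df.groupby("chrom"):
        merged = merge_intervals(zip(sub["start"], sub["end"]))
        gene_by_chrom[chrom] = (
            np.array([s for s, _ in merged]), np.array([e for _, e in merged]),
        )
    labels = []
    for r in tes.df.itertuples():
        intragenic = False
        if r.chrom in gene_by_chrom:
            starts, ends = gene_by_chrom[r.chrom]
            i = np.searchsorted(starts, r.end)
            intragenic = i > 0 and ends[i - 1] > r.start
        labels.append("intragenic" if intragenic else "intergenic")
    out = tes.df.copy()
    out["position_class"] = labels
    return out


# ---------------------------------------------------------------------------
# LTR insertion-time dating


def jc_correct(p) -> float:
    """Jukes-Cantor distance from a raw mismatch proportion."""
    p = np.asarray(p, dtype=float)
    out = np.where(p < 0.75, -0.75 * np.log(np.clip(1 - 4 * p / 3, 1e-300, None)),
                   np.nan)
    return out if out.ndim else float(out)


def insertion_time(K, mu: float = DEFAULT_MU):
    """T = K / (2 mu), in years."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(K, dtype=float) / (2 * mu)


def extract_ltr_pairs(tes: FeatureSet, genome: Genome) -> pd.DataFrame:
    """Pull 5'/3' LTR sequences for annotated LTR elements.

    Elements must carry an ``ltr_len`` attribute: the first/last ``ltr_len``
    bases of the element are its twin LTRs.
    """
    ltr_len = tes.attr("ltr_len")
    rows = []
    for (idx, r) in enumerate(tes.df.itertuples()):
        ll = ltr_len.iloc[idx]
        if pd.isna(ll) or r.te_order != "LTR":
            continue
        ll = int(ll)
        seq = genome[r.chrom]
        import re as _re

        m = _re.match(r"chr_(\d+)([A-Z])$", r.chrom)
        rows.append({
            "te_id": r.id, "chrom": r.chrom,
            "subgenome": m.group(2) if m else "unassigned",
            "ltr5": seq[r.start : r.start + ll],
            "ltr3": seq[r.end - ll : r.end],
        })
    return pd.DataFrame(rows, columns=["te_id", "chrom", "subgenome", "ltr5", "ltr3"])


def ltr_insertion_time(pairs: pd.DataFrame, mu: float = DEFAULT_MU):
    """Date LTR pairs: raw p (N-containing sites skipped), JC-corrected K,
    T = K/(2 mu); per-subgenome summary with empirical 95% CI of T.

    Pairs with p >= 0.75 are flagged saturated and excluded from the
    summary.  LTR pairs must be equal length (ungapped comparison).
    """
    out = pairs.copy()
    ps, flags = [], []
    for r in pairs.itertuples():
        a, b = encode(r.ltr5), encode(r.ltr3)
        if a.size != b.size:
            raise ValueError(f"LTR pair {getattr(r, 'te_id', '?')}: unequal lengths")
        ok = (a <= 3) & (b <= 3)
        n = int(ok.sum())
        p = float((a[ok] != b[ok]).sum() / n) if n else np.nan
        ps.append(p)
        flags.append(bool(p >= 0.75) if n else True)
    out["p"] = ps
    out["saturated"] = flags
    out["K"] = [np.nan if f else jc_correct(p) for p, f in zip(ps, flags)]
    out["T"] = [np.nan if not np.isfinite(k) else float(insertion_time(k, mu))
                for k in out["K"]]
    summ = []
    usable = out[~out["saturated"] & out["T"].notna()]
    for sub, g in usable.groupby("subgenome"):
        t = g["T"].to_numpy()
        summ.append({
            "subgenome": sub, "n": len(g), "median_T": float(np.median(t)),
            "ci_low": float(np.quantile(t, 0.025)),
            "ci_high": float(np.quantile(t, 0.975)),
            "mu": mu,
        })
    return out, pd.DataFrame(summ, columns=["subgenome", "n", "median_T",
                                            "ci_low", "ci_high", "mu"])
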