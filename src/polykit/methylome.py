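"""Weighted methylation levels, metagene profiles and gene-body-methylation
(gbM) classification.

The weighted level of a region is total methylated reads over total reads
(coverage-weighted, not a mean of per-site proportions) across
context-matching cytosines with coverage >= a floor (default 2).  Gene
methylation states are called per context with a one-sided binomial test of
the gene's methylated-site count against the site-level background rate of
coding regions, BH-corrected across genes within each context; gbM means CG
significant with CHG and CHH both non-significant.

Undefined is never reported as zero: regions with no eligible site return
NaN and genes without enough sites are "undetermined".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CytosineTable, FeatureSet, GenomicInterval, CONTEXTS


def binomial_tail(m: int, n: int, p0: float) -> float:
    """One-sided upper tail P(X >= m | n, p0) for X ~ Binomial(n, p0)."""
    if n == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, n, p0))


def _as_region_df(regions) -> pd.DataFrame:
    if isinstance(regions, FeatureSet):
        return regions.df[["chrom", "start", "end"]]
    if isinstance(regions, pd.DataFrame):
        return regions[["chrom", "start", "end"]]
    if isinstance(regions, GenomicInterval):
        regions = [regions]
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions]
    )


class _SiteIndex:
    """Per-chromosome sorted position index over a CytosineTable."""

    def __init__(self, cytosines: CytosineTable):
        df = cytosines.df
        self.cols = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos", kind="stable")
            self.cols[chrom] = {
                "pos0": sub["pos"].to_numpy() - 1,  # internal 0-based
                "n_meth": sub["n_meth"].to_numpy(),
                "cov": (sub["n_meth"] + sub["n_unmeth"]).to_numpy(),
                "context": sub["context"].to_numpy(),
                "strand": sub["strand"].to_numpy(),
            }

    def fetch(self, chrom, start, end):
        if chrom not in self.cols:
            return None
        c = self.cols[chrom]
        i, j = np.searchsorted(c["pos0"], (start, end))
        return {k: v[i:j] for k, v in c.items()}


def weighted_level(cytosines: CytosineTable, regions, context: str = "CG",
                   min_cov: int = 2):
    """Sum(n_meth) / Sum(coverage) over eligible sites inside the regions.

    Returns NaN (undefined) when no eligible site exists.  Aggregation is
    over numerators and denominators, so it is invariant to splitting a
    region into adjacent subregions.
    """
    num, den, _ = _weighted_parts(cytosines, regions, context, min_cov)
    return num / den if den else float("nan")


def _weighted_parts(cytosines, regions, context, min_cov):
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    idx = cytosines if isinstance(cytosines, _SiteIndex) else _SiteIndex(cytosines)
    num = den = n_sites = 0
    for r in _as_region_df(regions).itertuples():
        got = idx.fetch(r.chrom, r.start, r.end)
        if got is None:
            continue
        sel = (got["context"] == context) & (got["cov"] >= min_cov)
        num += int(got["n_meth"][sel].sum())
        den += int(got["cov"][sel].sum())
        n_sites += int(sel.sum())
    return num, den, n_sites


def region_levels(cytosines: CytosineTable, named_regions: dict,
                  min_cov: int = 2) -> pd.DataFrame:
    """Weighted level per (named region set, context) with site counts."""
    idx = _SiteIndex(cytosines)
    rows = []
    for name, regions in named_regions.items():
        for context in CONTEXTS:
            num, den, n_sites = _weighted_parts(idx, regions, context, min_cov)
            rows.append({
                "feature": name, "context": context,
                "level": num / den if den else np.nan, "n_sites": n_sites,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# background and site-level methylation calls


@dataclass
class BackgroundRates:
    """Background methylation of a reference region set (coding regions).

    ``p0``: read-weighted proportion per context; ``pi0``: fraction of
    eligible sites called methylated (the classifier consumes ``pi0``).
    """

    p0: dict
    pi0: dict
    n_sites: dict
    min_cov: int = 2
    error_rate: float = 0.005


def site_methylated(n_meth: np.ndarray, cov: np.ndarray,
                    error_rate: float = 0.005, site_alpha: float = 0.05) -> np.ndarray:
    """Binarize sites: a site is methylated when a one-sided binomial test
    of its methylated reads against the bisulfite non-conversion/error rate
    rejects at ``site_alpha``; sites too shallow for that test to ever
    reject fall back to a proportion >= 0.5 rule."""
    n_meth = np.asarray(n_meth)
    cov = np.asarray(cov)
    # smallest depth at which a fully methylated site can reject
    n_min = math.ceil(math.log(site_alpha) / math.log(error_rate)) if error_rate > 0 else 1
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.binom.sf(n_meth - 1, np.maximum(cov, 1), error_rate)
        fallback = np.where(cov > 0, n_meth / np.maximum(cov, 1) >= 0.5, False)
    return np.where(cov >= n_min, pvals < site_alpha, fallback) & (cov > 0)


def estimate_background(cytosines: CytosineTable, regions, min_cov: int = 2,
                        error_rate: float = 0.005,
                        site_alpha: float = 0.05) -> BackgroundRates:
    """Per-context background over a reference region set (coding regions
    by default usage).  Raises when a context has no eligible site."""
    idx = _SiteIndex(cytosines)
    region_df = _as_region_df(regions)
    if len(region_df) == 0:
        raise ValueError("background requires a non-empty region set")
    p0, pi0, n_sites = {}, {}, {}
    for context in CONTEXTS:
        num = den = called = total = 0
        for r in region_df.itertuples():
            got = idx.fetch(r.chrom, r.start, r.end)
            if got is None:
                continue
            sel = (got["context"] == context) & (got["cov"] >= min_cov)
            num += int(got["n_meth"][sel].sum())
            den += int(got["cov"][sel].sum())
            calls = site_methylated(got["n_meth"][sel], got["cov"][sel],
                                    error_rate, site_alpha)
            called += int(calls.sum())
            total += int(sel.sum())
        if total == 0:
            raise ValueError(f"no eligible {context} site in background regions")
        p0[context] = num / den
        pi0[context] = called / total
        n_sites[context] = total
    return BackgroundRates(p0=p0, pi0=pi0, n_sites=n_sites, min_cov=min_cov,
                           error_rate=error_rate)


# ---------------------------------------------------------------------------
# gbM classification


def classify_gbm(cytosines: CytosineTable, genes: FeatureSet,
                 background: BackgroundRates, alpha: float = 0.05,
                 min_sites: int = 5, min_cov: int = 2,
                 site_alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene methylation state by one-sided binomial tests per context.

    For each gene and context: n = eligible sites in the body, m = sites
    called methylated, p = P(X >= m | n, pi0_context); BH across genes
    within each context.  Classes: gbM (CG q < alpha, CHG and CHH q >=
    alpha), CHG/CHH-methylated, unmethylated, or undetermined when any
    context has n < min_sites (or the gene's chromosome is absent).
    """
    idx = _SiteIndex(cytosines)
    recs = []
    for r in genes.df.itertuples():
        rec = {"gene_id": r.id, "chrom": r.chrom}
        got = idx.fetch(r.chrom, r.start, r.end)
        for context in CONTEXTS:
            if got is None:
                n = m = 0
            else:
                sel = (got["context"] == context) & (got["cov"] >= min_cov)
                n = int(sel.sum())
                m = int(site_methylated(got["n_meth"][sel], got["cov"][sel],
                                        background.error_rate, site_alpha).sum())
            rec[f"n_{context}"] = n
            rec[f"m_{context}"] = m
            rec[f"p_{context}"] = (
                binomial_tail(m, n, background.pi0[context]) if n >= min_sites
                else np.nan
            )
        recs.append(rec)
    out = pd.DataFrame(recs)
    for context in CONTEXTS:
        p = out[f"p_{context}"].to_numpy()
        q = np.full(len(out), np.nan)
        defined = ~np.isnan(p)
        if defined.any():
            q[defined] = multipletests(p[defined], method="fdr_bh")[1]
        out[f"q_{context}"] = q

    classes = []
    for r in out.itertuples():
        ns = [getattr(r, f"n_{c}") for c in CONTEXTS]
        if any(n < min_sites for n in ns):
            classes.append("undetermined")
            continue
        sig = {c: getattr(r, f"q_{c}") < alpha for c in CONTEXTS}
        if sig["CHG"] or sig["CHH"]:
            classes.append("CHG/CHH-methylated")
        elif sig["CG"]:
            classes.append("gbM")
        else:
            classes.append("unmethylated")
    out["state"] = classes
    return out


def gbm_proportions(states: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """gbM count and fraction per labeled gene set.

    Undetermined genes are excluded from the denominator (their count is
    reported); an all-undetermined set has an undefined fraction.
    """
    lut = dict(zip(states["gene_id"], states["state"]))
    rows = []
    for label, ids in gene_sets.items():
        st = [lut.get(g, "undetermined") for g in ids]
        n_und = sum(s == "undetermined" for s in st)
        n_cls = len(st) - n_und
        n_gbm = sum(s == "gbM" for s in st)
        rows.append({
            "set": label, "n_genes": len(st), "n_classified": n_cls,
            "n_undetermined": n_und, "n_gbm": n_gbm,
            "fraction_gbm": n_gbm / n_cls if n_cls else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene profiles


def metagene_profile(cytosines: CytosineTable, features: FeatureSet,
                     flank: int = 1000, n_flank_bins: int = 10,
                     n_body_bins: int = 20, min_cov: int = 2) -> pd.DataFrame:
    """Aggregate weighted levels in fixed-width flank bins and
    length-normalised body bins around stranded features.

    The axis is reversed for minus-strand features so bin 0 is always the
    biological upstream edge; every eligible site falls in exactly one bin.
    """
    idx = _SiteIndex(cytosines)
    n_bins = 2 * n_flank_bins + n_body_bins
    num = {c: np.zeros(n_bins) for c in CONTEXTS}
    den = {c: np.zeros(n_bins) for c in CONTEXTS}
    cnt = {c: np.zeros(n_bins, dtype=np.int64) for c in CONTEXTS}
    for r in features.df.itertuples():
        got = idx.fetch(r.chrom, r.start - flank, r.end + flank)
        if got is None:
            continue
        pos = got["pos0"]
        eligible = got["cov"] >= min_cov
        body_len = r.end - r.start
        # signed coordinate relative to the feature, upstream negative
        if r.strand == "-":
            before = pos >= r.end  # 5' flank in biological orientation
            after = pos < r.start
            rel_body = (r.end - 1 - pos) / body_len
            rel_up = (pos - r.end) / flank
            rel_down = (r.start - 1 - pos) / flank
        else:
            before = pos < r.start
            after = pos >= r.end
            rel_body = (pos - r.start) / body_len
            rel_up = (r.start - 1 - pos) / flank  # 0 at TSS-1 increasing upstream
            rel_down = (pos - r.end) / flank
        bins = np.empty(pos.size, dtype=np.int64)
        up_bin = n_flank_bins - 1 - np.clip(
            (rel_up * n_flank_bins).astype(np.int64), 0, n_flank_bins - 1
        )
        body_bin = n_flank_bins + np.clip(
            (rel_body * n_body_bins).astype(np.int64), 0, n_body_bins - 1
        )
        down_bin = n_flank_bins + n_body_bins + np.clip(
            (rel_down * n_flank_bins).astype(np.int64), 0, n_flank_bins - 1
        )
        bins = np.where(before, up_bin, np.where(after, down_bin, body_bin))
        for context in CONTEXTS:
            sel = eligible & (got["context"] == context)
            np.add.at(num[context], bins[sel], got["n_meth"][sel])
            np.add.at(den[context], bins[sel], got["cov"][sel])
            np.add.at(cnt[context], bins[sel], 1)
    regions = (["upstream"] * n_flank_bins + ["body"] * n_body_bins
               + ["downstream"] * n_flank_bins)
    rows = []
    for context in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(den[context] > 0, num[context] / den[context], np.nan)
        for b in range(n_bins):
            rows.append({"bin": b, "region": regions[b], "context": context,
                         "level": level[b], "n_sites": int(cnt[context][b])})
    return pd.DataFrame(rows)
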