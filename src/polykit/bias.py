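"""Homeolog pairing and expression-bias classification.

Two callers mirror the two ways subgenome expression dominance is usually
summarised: a direct comparison of normalised abundance between the two
copies of each homeolog pair ("direct"), and an exact conditional binomial
test of the A-copy read count against the pair total with BH correction
("test").  A contingency summary associates bias classes with gene-body
methylation states of the favored/unfavored copies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureSet


# ---------------------------------------------------------------------------
# pairing


def _kmer_set(seq: str, k: int = 8) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _longest_increasing_subsequence(ranks: list[int]) -> set:
    """Indices of one longest strictly increasing subsequence."""
    import bisect

    tails, tails_idx, prev = [], [], [-1] * len(ranks)
    for i, v in enumerate(ranks):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = set()
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.add(i)
        i = prev[i]
    return out


def pair_homeologs(genes_a: FeatureSet, genes_x: FeatureSet, x_label: str,
                   cds: dict | None = None, mode: str = "sequence",
                   truth_pairs: pd.DataFrame | None = None, k: int = 8,
                   min_similarity: float = 0.05):
    """Pair genes of subgenome A with genes of subgenome X.

    ``truth`` mode reads the simulator's pairing table.  ``sequence`` mode
    is a documented simplification of synteny anchoring: reciprocal best
    match by shared CDS k-mer similarity (Jaccard, k=8) restricted to the
    matching homoeologous chromosome group, then filtered to pairs
    consistent with gene order (longest increasing subsequence of
    positional ranks per chromosome pair).

    Returns ``(pairs DataFrame, unpaired-A DataFrame)``.
    """
    if mode == "truth":
        if truth_pairs is None:
            raise ValueError("truth mode requires the simulator pairing table")
        sel = truth_pairs[truth_pairs["x"] == x_label].copy()
        sel["evidence"] = "truth"
        sel["order_consistent"] = True
        paired = set(sel["gene_a"])
        unpaired = genes_a.df[~genes_a.df["id"].isin(paired)][["id", "chrom"]]
        return sel, unpaired.rename(columns={"id": "gene_a"})
    if mode != "sequence":
        raise ValueError(f"unknown pairing mode {mode!r}")
    if cds is None:
        raise ValueError("sequence mode requires CDS sequences")

    import re as _re

    def group_of(chrom):
        m = _re.match(r"chr_(\d+)([A-Z])$", chrom)
        return int(m.group(1)) if m else None

    a_df = genes_a.df.assign(group=[group_of(c) for c in genes_a.df["chrom"]])
    x_df = genes_x.df.assign(group=[group_of(c) for c in genes_x.df["chrom"]])
    kms_a = {r.id: _kmer_set(cds[r.id], k) for r in a_df.itertuples() if r.id in cds}
    kms_x = {r.id: _kmer_set(cds[r.id], k) for r in x_df.itertuples() if r.id in cds}

    best_ax, best_xa = {}, {}
    for g in np.unique(a_df["group"].dropna()):
        a_ids = [r.id for r in a_df[a_df["group"] == g].itertuples() if r.id in kms_a]
        x_ids = [r.id for r in x_df[x_df["group"] == g].itertuples() if r.id in kms_x]
        for ai in a_ids:
            scores = []
            for xi in x_ids:
                inter = len(kms_a[ai] & kms_x[xi])
                union = len(kms_a[ai] | kms_x[xi])
                scores.append(inter / union if union else 0.0)
            if scores:
                j = int(np.argmax(scores))
                if scores[j] >= min_similarity:
                    best_ax[ai] = (x_ids[j], scores[j])
        for xi in x_ids:
            scores = []
            for ai in a_ids:
                inter = len(kms_a[ai] & kms_x[xi])
                union = len(kms_a[ai] | kms_x[xi])
                scores.append(inter / union if union else 0.0)
            if scores:
                j = int(np.argmax(scores))
                if scores[j] >= min_similarity:
                    best_xa[xi] = (a_ids[j], scores[j])

    rows = []
    for ai, (xi, score) in best_ax.items():
        if best_xa.get(xi, (None,))[0] == ai:
            rows.append({"gene_a": ai, "gene_x": xi, "x": x_label,
                         "similarity": score, "evidence": "reciprocal-best"})
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_x", "x", "similarity",
                                        "evidence"])

    # order-consistency: LIS of X positional ranks within each chromosome pair
    pos_a = dict(zip(a_df["id"], a_df["start"]))
    pos_x = dict(zip(x_df["id"], x_df["start"]))
    chrom_a = dict(zip(a_df["id"], a_df["chrom"]))
    chrom_x = dict(zip(x_df["id"], x_df["chrom"]))
    pairs["order_consistent"] = False
    for (ca, cx), grp in pairs.groupby(
        [pairs["gene_a"].map(chrom_a), pairs["gene_x"].map(chrom_x)]
    ):
        grp = grp.sort_values(by="gene_a", key=lambda s: s.map(pos_a))
        ranks = grp["gene_x"].map(pos_x).rank().astype(int).tolist()
        keep = _longest_increasing_subsequence(ranks)
        idx = [grp.index[i] for i in keep]
        pairs.loc[idx, "order_consistent"] = True
    pairs = pairs[pairs["order_consistent"]].reset_index(drop=True)
    pairs.insert(0, "pair_id", pairs["gene_a"] + ":" + pairs["x"])
    unpaired = a_df[~a_df["id"].isin(set(pairs["gene_a"]))][["id", "chrom"]]
    return pairs, unpaired.rename(columns={"id": "gene_a"})


# ---------------------------------------------------------------------------
# bias calling


def _side_libs(counts: pd.DataFrame, lib_sizes, side_lib_sizes):
    """Per-sample library sizes for the A and X sides.

    When the two homeolog copies were quantified against separate
    subgenome alignments their library sizes differ; ``side_lib_sizes``
    is then an ``(libs_A, libs_X)`` pair of per-sample totals.  Otherwise
    both sides share ``lib_sizes`` (column sums by default).
    """
    if side_lib_sizes is not None:
        la, lx = side_lib_sizes
        return pd.Series(la, index=counts.columns, dtype=float), \
            pd.Series(lx, index=counts.columns, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = pd.Series(lib_sizes, index=counts.columns, dtype=float)
    return lib_sizes, lib_sizes


def classify_bias_direct(pairs: pd.DataFrame, counts: pd.DataFrame,
                         normalization: str = "cpm",
                         lib_sizes: pd.Series | None = None,
                         side_lib_sizes: tuple | None = None):
    """Direct comparison of mean normalised abundance between copies.

    A pair is A-biased when the A copy's mean abundance exceeds the X
    copy's, X-biased in the converse, tied when equal (pairs with zero
    counts everywhere are tied and flagged).  Normalisation is counts per
    million on total library size by default; ``normalization="raw"``
    compares raw counts.  Returns (calls, summary).
    """
    libs_a, libs_x = _side_libs(counts, lib_sizes, side_lib_sizes)
    if normalization == "cpm":
        norm_a = counts.div(libs_a, axis=1) * 1e6
        norm_x = counts.div(libs_x, axis=1) * 1e6
    elif normalization == "raw":
        norm_a = norm_x = counts.astype(float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    rows = []
    for r in pairs.itertuples():
        a = float(norm_a.loc[r.gene_a].mean())
        x = float(norm_x.loc[r.gene_x].mean())
        zero = a == 0 and x == 0
        if zero:
            cls, lfc = "tied", 0.0
        else:
            with np.errstate(divide="ignore"):
                lfc = float(np.log2(a / x)) if x > 0 else float("inf")
                if a == 0:
                    lfc = float("-inf")
            cls = "A-biased" if a > x else ("X-biased" if x > a else "tied")
        rows.append({
            "pair_id": getattr(r, "pair_id", f"{r.gene_a}:{r.x}"),
            "gene_a": r.gene_a, "gene_x": r.gene_x, "x": r.x,
            "method": "direct", "class": cls, "log2fc": lfc,
            "zero_expression": zero,
        })
    calls = pd.DataFrame(rows)
    summary = _summarise(calls)
    return calls, summary


def classify_bias_test(pairs: pd.DataFrame, counts: pd.DataFrame,
                       alpha: float = 0.05, lib_sizes: pd.Series | None = None,
                       side_lib_sizes: tuple | None = None):
    """Exact conditional binomial test of summed A-copy counts.

    k = summed A counts, N = k + summed X counts, expected proportion
    pi = libA / (libA + libX) from total library sizes; two-sided exact
    p; BH across pairs; biased iff q < alpha, direction by observed vs
    expected.  N = 0 pairs are unbiased and flagged.
    """
    if counts.shape[1] < 2:
        raise ValueError("test method requires >= 2 replicates")
    libs_a, libs_x = _side_libs(counts, lib_sizes, side_lib_sizes)
    pi = float(libs_a.sum()) / float(libs_a.sum() + libs_x.sum())
    rows = []
    for r in pairs.itertuples():
        k = int(counts.loc[r.gene_a].sum())
        n = k + int(counts.loc[r.gene_x].sum())
        if n == 0:
            rows.append({
                "pair_id": getattr(r, "pair_id", f"{r.gene_a}:{r.x}"),
                "gene_a": r.gene_a, "gene_x": r.gene_x, "x": r.x,
                "method": "test", "k": k, "n": n, "p_value": np.nan,
                "log2fc": 0.0, "zero_expression": True,
            })
            continue
        p = stats.binomtest(k, n, pi, alternative="two-sided").pvalue
        with np.errstate(divide="ignore"):
            lfc = float(np.log2(k / (n - k))) if 0 < k < n else (
                float("inf") if k == n else float("-inf")
            )
        rows.append({
            "pair_id": getattr(r, "pair_id", f"{r.gene_a}:{r.x}"),
            "gene_a": r.gene_a, "gene_x": r.gene_x, "x": r.x,
            "method": "test", "k": k, "n": n, "p_value": float(p),
            "log2fc": lfc, "zero_expression": False,
        })
    calls = pd.DataFrame(rows)
    q = np.full(len(calls), np.nan)
    defined = calls["p_value"].notna().to_numpy()
    if defined.any():
        q[defined] = multipletests(calls.loc[defined, "p_value"], method="fdr_bh")[1]
    calls["q_value"] = q
    cls = []
    for r in calls.itertuples():
        if not np.isfinite(r.q_value) or r.q_value >= alpha:
            cls.append("unbiased")
        else:
            cls.append("A-biased" if r.k / r.n > pi else "X-biased")
    calls["class"] = cls
    summary = _summarise(calls, tied_label="unbiased")
    return calls, summary


def _summarise(calls: pd.DataFrame, tied_label: str = "tied") -> pd.DataFrame:
    rows = []
    for x, grp in calls.groupby("x"):
        n = len(grp)
        n_a = int((grp["class"] == "A-biased").sum())
        n_x = int((grp["class"] == "X-biased").sum())
        rows.append({
            "x": x, "n_pairs": n, "n_A_biased": n_a, "n_X_biased": n_x,
            f"n_{tied_label}": n - n_a - n_x,
            "fraction_A_biased": n_a / n if n else np.nan,
            "fraction_X_biased": n_x / n if n else np.nan,
        })
    out = pd.DataFrame(rows)
    if len(out):
        med = {"x": "median", "n_pairs": int(out["n_pairs"].median()),
               "n_A_biased": float(out["n_A_biased"].median()),
               "n_X_biased": float(out["n_X_biased"].median()),
               f"n_{tied_label}": float(out[f"n_{tied_label}"].median()),
               "fraction_A_biased": float(out["fraction_A_biased"].median()),
               "fraction_X_biased": float(out["fraction_X_biased"].median())}
        out = pd.concat([out, pd.DataFrame([med])], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# bias x gbM association


def bias_gbm_association(bias_calls: pd.DataFrame, gbm_states: pd.DataFrame,
                         top_n: int = 1000, rank_by: str = "log2fc") -> pd.DataFrame:
    """gbM composition of favored vs unfavored copies of top biased pairs.

    Selects up to ``top_n`` pairs per bias class ranked by |log2FC| (ties
    by pair id); reports gbM fractions for the favored and unfavored copy
    and a 2x2 Fisher exact test of (favored copy gbM) x (bias direction).
    """
    if rank_by != "log2fc":
        raise ValueError("only |log2fc| ranking is implemented")
    state = dict(zip(gbm_states["gene_id"], gbm_states["state"]))

    def is_gbm(gid):
        return state.get(gid) == "gbM"

    rows = []
    table = {}
    for cls in ("A-biased", "X-biased"):
        grp = bias_calls[bias_calls["class"] == cls].copy()
        grp["rank_key"] = grp["log2fc"].abs()
        grp = grp.sort_values(["rank_key", "pair_id"],
                              ascending=[False, True]).head(top_n)
        fav_col, unfav_col = (("gene_a", "gene_x") if cls == "A-biased"
                              else ("gene_x", "gene_a"))
        fav = [is_gbm(g) for g in grp[fav_col]]
        unfav = [is_gbm(g) for g in grp[unfav_col]]
        fav_und = [state.get(g, "undetermined") == "undetermined"
                   for g in grp[fav_col]]
        unfav_und = [state.get(g, "undetermined") == "undetermined"
                     for g in grp[unfav_col]]
        n_fav = len(fav) - sum(fav_und)
        n_unfav = len(unfav) - sum(unfav_und)
        table[cls] = (sum(fav), len(fav) - sum(fav))
        rows.append({
            "class": cls, "n_selected": len(grp),
            "n_gbm_favored": int(sum(fav)), "n_gbm_unfavored": int(sum(unfav)),
            "fraction_gbm_favored": sum(fav) / n_fav if n_fav else np.nan,
            "fraction_gbm_unfavored": sum(unfav) / n_unfav if n_unfav else np.nan,
        })
    out = pd.DataFrame(rows)
    if all(c in table for c in ("A-biased", "X-biased")):
        mat = np.array([table["A-biased"], table["X-biased"]])
        if mat.sum() > 0:
            odds, p = stats.fisher_exact(mat)
            # report infinite odds ratios as such rather than NaN
            a, b = mat[0]
            c, d = mat[1]
            if b == 0 or c == 0:
                odds = float("inf") if (a > 0 and d >= 0) else odds
            out["odds_ratio"] = odds
            out["fisher_p"] = p
    return out
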