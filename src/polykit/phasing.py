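"""Subgenome phasing from differential k-mers.

Chromosome-by-k-mer counting, selection of k-mers that are differentially
abundant within homoeologous chromosome groups, k-means clustering of the
resulting frequency profiles (with PCA and silhouette diagnostics),
per-window enrichment of subgenome-specific k-mer sets, and a
neighbour-joining tree over subgenome consensus profiles.  The tree is a
distance-based heuristic stand-in for a phylogeny, not a likelihood method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score, silhouette_samples
from statsmodels.stats.multitest import multipletests

from .io import Genome
from ._seq import encode, kmer_codes, canonical_codes, decode_kmer


@dataclass
class KmerMatrix:
    """Chromosome x k-mer occurrence counts.

    ``kmers`` are sorted uint64 2-bit codes (canonical = lexicographic min of
    the k-mer and its reverse complement when ``canonical``); ``counts`` has
    one row per chromosome.
    """

    k: int
    canonical: bool
    chroms: list[str]
    chrom_lens: np.ndarray  # bases per chromosome
    groups: np.ndarray  # homoeologous group per chromosome
    subgenomes: list  # truth labels when chromosome names carry them, else None
    kmers: np.ndarray  # (n_kmers,) uint64, sorted
    counts: np.ndarray  # (n_chroms, n_kmers) int64

    @property
    def shape(self):
        return self.counts.shape

    def frequencies(self) -> np.ndarray:
        """Counts per Mb, normalised by chromosome length."""
        return self.counts / self.chrom_lens[:, None] * 1e6

    def kmer_strings(self) -> list[str]:
        return [decode_kmer(c, self.k) for c in self.kmers]

    def subset(self, col_mask) -> "KmerMatrix":
        return KmerMatrix(
            self.k, self.canonical, list(self.chroms), self.chrom_lens.copy(),
            self.groups.copy(), list(self.subgenomes),
            self.kmers[col_mask], self.counts[:, col_mask],
        )


def _chrom_kmer_counts(seq: str, k: int, canonical: bool):
    codes = encode(seq)
    _, fwd, rc = kmer_codes(codes, k)
    keys = canonical_codes(fwd, rc) if canonical else fwd
    return np.unique(keys, return_counts=True)


def count_kmers(genome: Genome, k: int = 15, canonical: bool = True,
                min_total: int = 10) -> KmerMatrix:
    """Count all k-mers per chromosome, keeping those whose genome-wide
    total is at least ``min_total``.  Windows containing N are skipped."""
    if not (3 <= k <= 31 and k % 2 == 1):
        raise ValueError("k must be odd and in [3, 31]")
    unlabeled = [n for n in genome.names if n not in genome.labels]
    if unlabeled:
        raise ValueError(
            f"chromosomes without parsed group/subgenome labels: {unlabeled}; "
            "differential selection requires homoeologous groups"
        )
    per_chrom = [
        _chrom_kmer_counts(genome[name], k, canonical) for name in genome.names
    ]
    all_keys = np.unique(np.concatenate([u for u, _ in per_chrom]))
    totals = np.zeros(all_keys.size, dtype=np.int64)
    for u, c in per_chrom:
        totals[np.searchsorted(all_keys, u)] += c
    keep = totals >= min_total
    kept = all_keys[keep]
    counts = np.zeros((len(per_chrom), kept.size), dtype=np.int64)
    for i, (u, c) in enumerate(per_chrom):
        idx = np.searchsorted(kept, u)
        ok = (idx < kept.size) & (kept[np.minimum(idx, kept.size - 1)] == u)
        counts[i, idx[ok]] = c[ok]
    return KmerMatrix(
        k=k, canonical=canonical, chroms=list(genome.names),
        chrom_lens=np.array([genome.length(n) for n in genome.names]),
        groups=np.array([genome.group(n) for n in genome.names]),
        subgenomes=[genome.subgenome(n) for n in genome.names],
        kmers=kept, counts=counts,
    )


def select_differential_kmers(matrix: KmerMatrix, min_fold: float = 2.0,
                              min_freq: float = 5.0,
                              min_groups: int | None = None) -> KmerMatrix:
    """Keep k-mers differentially abundant within homoeologous groups.

    A k-mer passes in a group when its maximum per-Mb frequency over the
    group's chromosomes is >= ``min_fold`` times its minimum and >=
    ``min_freq``; it is kept when it passes in at least ``min_groups``
    groups (default: half the groups, rounded up).
    """
    freqs = matrix.frequencies()
    group_ids = np.unique(matrix.groups)
    for g in group_ids:
        if (matrix.groups == g).sum() < 2:
            raise ValueError(f"homoeologous group {g} has fewer than 2 chromosomes")
    if min_groups is None:
        min_groups = int(np.ceil(len(group_ids) / 2))
    n_pass = np.zeros(matrix.kmers.size, dtype=np.int64)
    for g in group_ids:
        sub = freqs[matrix.groups == g]
        mx, mn = sub.max(axis=0), sub.min(axis=0)
        n_pass += ((mx >= min_fold * mn) & (mx >= min_freq)).astype(np.int64)
    keep = n_pass >= min_groups
    out = matrix.subset(keep)
    if out.kmers.size == 0:
        warnings.warn("no differential k-mers found; downstream assignment "
                      "will be empty/non-separable")
    return out


@dataclass
class SubgenomeAssignment:
    """Chromosome -> cluster/subgenome assignment with diagnostics."""

    assignments: pd.DataFrame  # chrom, cluster, subgenome, silhouette
    pca: pd.DataFrame  # chrom, PC1.., cluster, subgenome
    specific_kmers: dict  # subgenome label -> sorted uint64 codes
    silhouette: float
    inertia: float
    non_separable: bool
    k: int = 15
    canonical: bool = True
    cluster_profiles: pd.DataFrame | None = None  # label x kmer mean frequency

    @property
    def labels(self) -> dict:
        return dict(zip(self.assignments["chrom"], self.assignments["subgenome"]))


def _empty_assignment(chroms, k, canonical) -> SubgenomeAssignment:
    df = pd.DataFrame({"chrom": chroms, "cluster": -1, "subgenome": "NA",
                       "silhouette": np.nan})
    return SubgenomeAssignment(
        assignments=df, pca=pd.DataFrame({"chrom": chroms}), specific_kmers={},
        silhouette=float("nan"), inertia=float("nan"), non_separable=True,
        k=k, canonical=canonical,
    )


def cluster_subgenomes(diff_matrix: KmerMatrix, n_subgenomes: int = 4,
                       seed: int = 42, n_init: int = 20, min_fold: float = 2.0,
                       separability_threshold: float = 0.25,
                       truth: dict | None = None) -> SubgenomeAssignment:
    """K-means over scaled differential k-mer profiles.

    Cluster labels are mapped to subgenome names by majority truth label
    when chromosome names carry one, else stable labels SG1..SGn.  An
    assignment with silhouette below ``separability_threshold`` (or with no
    differential k-mers at all) is flagged non-separable.
    """
    chroms = diff_matrix.chroms
    if diff_matrix.kmers.size == 0:
        return _empty_assignment(chroms, diff_matrix.k, diff_matrix.canonical)
    if n_subgenomes > len(chroms):
        raise ValueError("more subgenomes requested than chromosomes")
    X = diff_matrix.frequencies()
    km = KMeans(n_clusters=n_subgenomes, n_init=n_init, random_state=seed)
    cluster = km.fit_predict(X)
    n_pc = min(len(chroms) - 1, X.shape[1], 10)
    coords = PCA(n_components=n_pc, random_state=seed).fit_transform(X)
    if 1 < n_subgenomes < len(chroms) and len(set(cluster)) > 1:
        sil = float(silhouette_score(X, cluster))
        sil_samples = silhouette_samples(X, cluster)
    else:
        sil, sil_samples = float("nan"), np.full(len(chroms), np.nan)

    # map clusters to names
    names = {}
    if truth is None:
        truth_labels = diff_matrix.subgenomes
        if any(s is None for s in truth_labels):
            truth_labels = None
    else:
        truth_labels = [truth.get(c) for c in chroms]
    order = []
    for c in range(n_subgenomes):
        members = np.nonzero(cluster == c)[0]
        order.append((members.min() if members.size else len(chroms), c))
    order.sort()
    for rank, (_, c) in enumerate(order):
        if truth_labels is not None:
            members = [truth_labels[i] for i in np.nonzero(cluster == c)[0]]
            if members:
                vals, cnts = np.unique(members, return_counts=True)
                names[c] = str(vals[np.argmax(cnts)])
                continue
        names[c] = f"SG{rank + 1}"

    # cluster-specific k-mer sets: mean frequency >= min_fold x any other cluster
    means = np.vstack([X[cluster == c].mean(axis=0) for c in range(n_subgenomes)])
    specific = {}
    for c in range(n_subgenomes):
        others = np.delete(means, c, axis=0)
        mask = means[c] >= min_fold * others.max(axis=0)
        specific[names[c]] = np.sort(diff_matrix.kmers[mask])

    assignments = pd.DataFrame({
        "chrom": chroms, "cluster": cluster,
        "subgenome": [names[c] for c in cluster], "silhouette": sil_samples,
    })
    pca_df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    pca_df.insert(0, "chrom", chroms)
    pca_df["cluster"] = cluster
    pca_df["subgenome"] = assignments["subgenome"]
    profiles = pd.DataFrame(means, index=[names[c] for c in range(n_subgenomes)])
    return SubgenomeAssignment(
        assignments=assignments, pca=pca_df, specific_kmers=specific,
        silhouette=sil, inertia=float(km.inertia_),
        non_separable=bool(np.isnan(sil) or sil < separability_threshold),
        k=diff_matrix.k, canonical=diff_matrix.canonical,
        cluster_profiles=profiles,
    )


def window_enrichment(assignment: SubgenomeAssignment, genome: Genome,
                      window: int = 1_000_000, alpha: float = 0.05) -> pd.DataFrame:
    """Per-window counts/proportions of each subgenome-specific k-mer set.

    A window on a chromosome assigned to subgenome ``s`` is flagged enriched
    when its ``s``-specific k-mer count is over-represented relative to the
    genome-wide proportion of the ``s`` set (one-sided binomial test,
    BH-corrected over all windows).  Windows with no diagnostic k-mer have
    undefined proportions and no flag.
    """
    sets = {lab: np.asarray(km) for lab, km in assignment.specific_kmers.items()
            if np.asarray(km).size}
    labels = sorted(sets)
    own = assignment.labels
    k = assignment.k
    rows = []
    for chrom in genome.names:
        L = genome.length(chrom)
        w = window if window <= L else L
        codes = encode(genome[chrom])
        starts, fwd, rc = kmer_codes(codes, k)
        keys = canonical_codes(fwd, rc) if assignment.canonical else fwd
        win_idx = starts // w
        n_win = int(np.ceil(L / w))
        per_set = {}
        for lab in labels:
            member = np.searchsorted(sets[lab], keys)
            member = (member < sets[lab].size) & (
                sets[lab][np.minimum(member, sets[lab].size - 1)] == keys
            )
            cnt = np.zeros(n_win, dtype=np.int64)
            np.add.at(cnt, win_idx[member], 1)
            per_set[lab] = cnt
        for wi in range(n_win):
            row = {"chrom": chrom, "start": wi * w, "end": min((wi + 1) * w, L),
                   "subgenome": own.get(chrom, "NA")}
            total = int(sum(per_set[lab][wi] for lab in labels))
            row["total"] = total
            for lab in labels:
                row[f"count_{lab}"] = int(per_set[lab][wi])
                row[f"prop_{lab}"] = per_set[lab][wi] / total if total else np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty or not labels:
        df["p_value"] = np.nan
        df["q_value"] = np.nan
        df["enriched"] = False
        return df

    # genome-wide proportion per set
    grand_total = sum(df[f"count_{lab}"].sum() for lab in labels)
    p0 = {lab: (df[f"count_{lab}"].sum() / grand_total if grand_total else np.nan)
          for lab in labels}
    pvals = np.full(len(df), np.nan)
    for i, row in enumerate(df.itertuples()):
        lab = row.subgenome
        if lab not in sets or row.total == 0:
            continue
        own_count = getattr(row, f"count_{lab}")
        pvals[i] = stats.binom.sf(own_count - 1, row.total, p0[lab])
    df["p_value"] = pvals
    q = np.full(len(df), np.nan)
    defined = ~np.isnan(pvals)
    if defined.any():
        q[defined] = multipletests(pvals[defined], method="fdr_bh")[1]
    df["q_value"] = q
    df["enriched"] = (q < alpha) & defined
    return df


def subgenome_tree(profiles, outgroup: str | None = None) -> str:
    """Neighbour-joining Newick tree from mean k-mer frequency profiles.

    ``profiles`` is a DataFrame (rows = subgenome labels) or a
    SubgenomeAssignment; distances are 1 - cosine similarity.  This is a
    heuristic distance-based stand-in for a phylogeny.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(profiles, SubgenomeAssignment):
        profiles = profiles.cluster_profiles
    if profiles is None or len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a tree")
    X = profiles.to_numpy(dtype=float)
    ids = [str(i) for i in profiles.index]
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    cos = (X @ X.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(cos, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    tree = nj(DistanceMatrix(d, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if outgroup is not None:
        tip = tree.find(outgroup)
        tree = tree.root_at(tip.parent)
    buf = tree.__str__()
    return buf if buf.endswith("\n") else buf + "\n"


def nj_tree_from_distances(d: np.ndarray, ids: list[str]) -> str:
    """Neighbour joining on an explicit distance matrix (Newick output)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(np.asarray(d, dtype=float), ids))
    s = str(tree)
    return s if s.endswith("\n") else s + "\n"
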