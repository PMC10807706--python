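"""Differential k-mer phasing: counting, selection, clustering, windows, NJ."""

import io as stdio

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polykit import io as pio
from polykit._seq import revcomp, decode_kmer
from polykit.phasing import (
    KmerMatrix, count_kmers, select_differential_kmers, cluster_subgenomes,
    window_enrichment, subgenome_tree, nj_tree_from_distances,
)


def _genome(seqs):
    return pio.Genome(seqs)


def test_count_kmers_hand_enumeration():
    g = _genome({"chr_1A": "ACGTACGT"})
    mat = count_kmers(g, k=3, canonical=False, min_total=1)
    got = dict(zip(mat.kmer_strings(), mat.counts[0]))
    assert got == {"ACG": 2, "CGT": 2, "GTA": 1, "TAC": 1}


def test_count_kmers_canonical_merges_revcomp():
    g = _genome({"chr_1A": "ACGTACGT"})
    mat = count_kmers(g, k=3, canonical=True, min_total=1)
    got = dict(zip(mat.kmer_strings(), mat.counts[0]))
    # ACG merges with its reverse complement CGT
    assert got["ACG"] == 4
    assert "CGT" not in got


def test_count_kmers_skips_n_windows():
    g = _genome({"chr_1A": "ACGNACG"})
    mat = count_kmers(g, k=3, canonical=False, min_total=1)
    assert sum(mat.counts[0]) == 2  # only the two N-free windows


def test_count_kmers_rejects_unlabeled():
    g = _genome({"scaffold_1": "ACGTACGT"})
    with pytest.raises(ValueError, match="scaffold_1"):
        count_kmers(g, k=3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=20, max_size=200))
def test_canonical_counts_strand_invariant(seq):
    """count(seq) == count(revcomp(seq)) for every canonical k-mer."""
    g1 = _genome({"chr_1A": seq})
    g2 = _genome({"chr_1A": revcomp(seq)})
    m1 = count_kmers(g1, k=5, canonical=True, min_total=1)
    m2 = count_kmers(g2, k=5, canonical=True, min_total=1)
    assert dict(zip(m1.kmers, m1.counts[0])) == dict(zip(m2.kmers, m2.counts[0]))


def _matrix_from_counts(counts, chrom_len=1_000_000):
    counts = np.asarray(counts)
    n = counts.shape[0]
    return KmerMatrix(
        k=15, canonical=True,
        chroms=[f"chr_1{s}" for s in "ABCD"[:n]],
        chrom_lens=np.full(n, chrom_len), groups=np.ones(n, dtype=int),
        subgenomes=list("ABCD"[:n]),
        kmers=np.arange(counts.shape[1], dtype=np.uint64), counts=counts,
    )


def test_differential_selection_rules():
    # per-Mb frequencies on 1-Mb chromosomes equal the raw counts
    mat = _matrix_from_counts(np.array([
        [100, 50],
        [100, 1],
        [100, 1],
        [100, 1],
    ]))
    out = select_differential_kmers(mat, min_fold=2.0, min_freq=5.0, min_groups=1)
    # flat (100,100,100,100) excluded; (50,1,1,1) included
    assert out.kmers.tolist() == [1]


def test_differential_selection_min_freq():
    mat = _matrix_from_counts(np.array([[4], [1], [1], [1]]))
    out = select_differential_kmers(mat, min_fold=2.0, min_freq=5.0, min_groups=1)
    assert out.kmers.size == 0  # differential but below min_freq


def test_differential_requires_two_chroms_per_group():
    mat = _matrix_from_counts(np.array([[1, 2]]))
    with pytest.raises(ValueError, match="fewer than 2"):
        select_differential_kmers(mat)


def test_clustering_recovers_subgenomes(default_sim, default_assignment):
    from sklearn.metrics import adjusted_rand_score

    truth = [default_sim.genome.subgenome(c)
             for c in default_assignment.assignments["chrom"]]
    ari = adjusted_rand_score(truth, default_assignment.assignments["cluster"])
    assert ari == 1.0
    assert not default_assignment.non_separable
    # majority-truth naming: every chromosome is labeled its own subgenome
    for r in default_assignment.assignments.itertuples():
        assert r.subgenome == default_sim.genome.subgenome(r.chrom)


def test_pc1_separates_one_subgenome(default_sim, default_assignment):
    """The first principal component isolates one subgenome cluster
    from the other three (the deep-split progenitor geometry)."""
    pca = default_assignment.pca
    ranges = {}
    for sub, grp in pca.groupby("subgenome"):
        ranges[sub] = (grp["PC1"].min(), grp["PC1"].max())
    isolated = 0
    for sub, (lo, hi) in ranges.items():
        others = [v for s, v in ranges.items() if s != sub]
        if all(hi < olo or lo > ohi for olo, ohi in others):
            rest = [x for s, (a, b) in ranges.items() if s != sub for x in (a, b)]
            if hi < min(rest) or lo > max(rest):
                isolated += 1
    assert isolated >= 1


def test_specific_kmer_sets_disjoint_and_truthful(default_sim, default_assignment,
                                                  default_kmer_matrix):
    sets = default_assignment.specific_kmers
    labels = list(sets)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            assert np.intersect1d(sets[a], sets[b]).size == 0
    # the chromosome with maximum frequency of a specific k-mer belongs to
    # the set's own subgenome
    diff = select_differential_kmers(default_kmer_matrix)
    freqs = diff.frequencies()
    rng = np.random.default_rng(0)
    for lab in labels:
        idx = np.searchsorted(diff.kmers, sets[lab])
        sample = rng.choice(idx, size=min(200, idx.size), replace=False)
        for j in sample:
            top = int(np.argmax(freqs[:, j]))
            assert default_sim.genome.subgenome(diff.chroms[top]) == lab


def test_no_signal_genome_flagged_non_separable(small_config):
    import warnings
    from polykit.sim import SimConfig, simulate_genome

    cfg = SimConfig(**{**vars(small_config), "te_families_per_subgenome": 0})
    sim = simulate_genome(cfg)
    mat = count_kmers(sim.genome, k=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff = select_differential_kmers(mat)
    asg = cluster_subgenomes(diff)
    assert asg.non_separable
    assert np.isnan(asg.silhouette) or asg.silhouette < 0.25


def test_empty_matrix_gives_empty_assignment():
    mat = _matrix_from_counts(np.zeros((4, 0), dtype=int))
    asg = cluster_subgenomes(mat)
    assert asg.non_separable
    assert (asg.assignments["subgenome"] == "NA").all()


def test_window_enrichment_props_and_flags(default_sim, default_assignment):
    wins = window_enrichment(default_assignment, default_sim.genome, window=50_000)
    labels = sorted(default_assignment.specific_kmers)
    props = wins[[f"prop_{l}" for l in labels]]
    defined = wins["total"] > 0
    # proportions sum to 1 where defined, are NaN elsewhere (no flags there)
    assert np.allclose(props[defined].sum(axis=1), 1.0)
    assert props[~defined].isna().all().all()
    assert not wins.loc[~defined, "enriched"].any()
    # windows holding own-subgenome k-mers are detected on every chromosome
    flagged = wins[wins["enriched"]]
    assert set(flagged["chrom"]) == set(default_sim.genome.names)
    for r in flagged.itertuples():
        assert r.subgenome == default_sim.genome.subgenome(r.chrom)


def test_window_enrichment_dies_under_label_permutation(default_sim,
                                                        default_assignment):
    """Rotating the chromosome->subgenome labels destroys enrichment."""
    import copy

    wins = window_enrichment(default_assignment, default_sim.genome, window=50_000)
    n_flags = int(wins["enriched"].sum())
    assert n_flags > 0
    rot = {"A": "B", "B": "C", "C": "D", "D": "A"}
    shuffled = copy.deepcopy(default_assignment)
    shuffled.assignments["subgenome"] = [
        rot[s] for s in shuffled.assignments["subgenome"]
    ]
    wins_null = window_enrichment(shuffled, default_sim.genome, window=50_000)
    assert wins_null["enriched"].sum() <= 0.05 * n_flags


def test_window_larger_than_chromosome_is_single_window(default_assignment):
    g = pio.Genome({"chr_1A": "ACGT" * 2500})
    wins = window_enrichment(default_assignment, g, window=10**9)
    assert len(wins) == 1
    assert wins.loc[0, "end"] == 10_000


def _splits(newick):
    from skbio import TreeNode

    tree = TreeNode.read(stdio.StringIO(newick))
    tips = {t.name for t in tree.tips()}
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        out.add(min(side, frozenset(tips - side), key=sorted))
    return out


def test_subgenome_tree_recovers_planted_quartet(default_assignment):
    nwk = subgenome_tree(default_assignment)
    assert frozenset({"A", "B"}) in _splits(nwk) or frozenset({"C", "D"}) in _splits(nwk)


def test_nj_exact_on_additive_distances():
    """NJ reproduces tip-to-tip path lengths of the generating tree."""
    from skbio import TreeNode

    # tree ((a:2,b:3):1,(c:1.5,d:4):2) -> additive distance matrix
    d = np.array([
        [0, 5, 6.5, 9],
        [5, 0, 7.5, 10],
        [6.5, 7.5, 0, 5.5],
        [9, 10, 5.5, 0],
    ])
    ids = ["a", "b", "c", "d"]
    nwk = nj_tree_from_distances(d, ids)
    tree = TreeNode.read(stdio.StringIO(nwk))
    for i, u in enumerate(ids):
        for j, v in enumerate(ids):
            if i < j:
                assert tree.find(u).distance(tree.find(v)) == pytest.approx(d[i, j])
    assert frozenset({"a", "b"}) in _splits(nwk)


def test_identical_profiles_zero_length_cherry():
    profiles = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]],
                            index=["p", "q", "r"])
    nwk = subgenome_tree(profiles)
    from skbio import TreeNode

    tree = TreeNode.read(stdio.StringIO(nwk))
    assert tree.find("p").distance(tree.find("q")) == pytest.approx(0.0)


def test_three_profiles_terminate():
    profiles = pd.DataFrame(np.eye(3), index=["x", "y", "z"])
    nwk = subgenome_tree(profiles)
    assert sorted(_tip_names(nwk)) == ["x", "y", "z"]


def _tip_names(newick):
    from skbio import TreeNode

    return [t.name for t in TreeNode.read(stdio.StringIO(newick)).tips()]


def test_tree_needs_three_profiles():
    with pytest.raises(ValueError, match="3 profiles"):
        subgenome_tree(pd.DataFrame(np.eye(2), index=["x", "y"]))


def test_seed_determinism_of_clustering(default_kmer_matrix):
    diff = select_differential_kmers(default_kmer_matrix)
    a1 = cluster_subgenomes(diff, seed=42)
    a2 = cluster_subgenomes(diff, seed=42)
    pd.testing.assert_frame_equal(a1.assignments, a2.assignments)


def test_diagnostic_motif_kmer_arithmetic(default_sim, default_kmer_matrix):
    """Each family-private 31-bp seed motif contributes its full set of
    31 - 15 + 1 = 17 diagnostic 15-mers to the differential matrix."""
    from polykit.sim import parse_topology, _build_te_library
    from polykit._seq import decode, encode, kmer_codes, canonical_codes

    cfg = default_sim.config
    tree = parse_topology(cfg.topology, cfg.subgenomes)
    families = _build_te_library(cfg, tree)
    diff = select_differential_kmers(default_kmer_matrix)
    kset = set(diff.kmers.tolist())
    for fam in families:
        if not fam["ltr"]:
            continue
        for sub, parts in fam["per_leaf"].items():
            _, fwd, rc = kmer_codes(parts["motif"], 15)
            canon = canonical_codes(fwd, rc)
            assert canon.size == 31 - 15 + 1
            present = sum(int(c) in kset for c in canon)
            assert present == 17
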