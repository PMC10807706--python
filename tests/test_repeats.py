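"""Telomere/monomer detection, TE landscape, distances, LTR dating."""

import numpy as np
import pandas as pd
import pytest

from polykit import io as pio
from polykit import repeats as R
from polykit._seq import decode, encode, mutate, revcomp


def _rand_seq(n, seed):
    return decode(np.random.default_rng(seed).integers(0, 4, n, dtype=np.uint8))


# ---------------------------------------------------------------------------
# telomeres


def test_telomere_planted_both_ends():
    seq = "TTTAGGG" * 30 + _rand_seq(10_000, 0) + "CCCTAAA" * 30
    g = pio.Genome({"chr_1A": seq})
    calls = R.find_telomeres(g)
    assert len(calls) == 2
    assert sorted(calls["end"]) == ["3p", "5p"]
    assert calls["copies"].tolist() == [30, 30]
    five = calls[calls["end"] == "5p"].iloc[0]
    assert (five["start"], five["stop"]) == (0, 210)


def test_telomere_absent_on_random_sequence():
    g = pio.Genome({"chr_1A": _rand_seq(10_000, 1)})
    assert len(R.find_telomeres(g)) == 0


def test_telomere_tolerates_one_mismatch_per_copy():
    unit = "TTTAGGG"
    mutated = "".join(
        (unit[:3] + "C" + unit[4:]) if i % 2 else unit for i in range(30)
    )
    g = pio.Genome({"chr_1A": mutated + _rand_seq(5000, 2)})
    calls = R.find_telomeres(g)
    assert len(calls) == 1 and calls.iloc[0]["copies"] == 30


def test_telomere_default_sim_all_planted_ends(default_sim):
    calls = R.find_telomeres(default_sim.genome)
    truth = default_sim.truth.telomeres
    assert len(calls) == len(truth) == 56
    got = set(zip(calls["chrom"], calls["end"]))
    assert got == set(zip(truth["chrom"], truth["end"]))


def test_telomere_input_validation():
    g = pio.Genome({"chr_1A": "ACGT" * 100})
    with pytest.raises(ValueError, match="motif"):
        R.find_telomeres(g, motif="")
    with pytest.raises(ValueError, match="end_window"):
        R.find_telomeres(g, end_window=10)


# ---------------------------------------------------------------------------
# tandem monomer


def test_monomer_clean_array_exact():
    unit = _rand_seq(147, 3)
    calls = R.detect_tandem_monomer(unit * 100)
    assert len(calls) == 1
    c = calls[0]
    assert (c.period, c.copies, c.identity) == (147, 100.0, 1.0)
    assert c.consensus == unit


def test_monomer_robust_to_two_percent_mutation():
    rng = np.random.default_rng(4)
    unit = _rand_seq(147, 5)
    seq = _rand_seq(4000, 6) + decode(mutate(encode(unit * 100), 0.02, rng)) \
        + _rand_seq(4000, 7)
    calls = R.detect_tandem_monomer(seq)
    assert len(calls) == 1
    assert calls[0].period == 147
    assert calls[0].identity >= 0.95


def test_monomer_prefers_smallest_period_among_multiples():
    unit = _rand_seq(60, 8)
    calls = R.detect_tandem_monomer(unit * 80, period_min=50, period_max=200)
    assert [c.period for c in calls] == [60]


def test_monomer_zero_calls_on_random_negatives():
    for seed in range(20):
        assert R.detect_tandem_monomer(_rand_seq(15_000, 100 + seed)) == []


def test_monomer_recall_on_clean_planted_arrays():
    """100% recall across unit lengths at default thresholds."""
    for i, period in enumerate((52, 80, 111, 147, 199)):
        unit = _rand_seq(period, 200 + i)
        seq = _rand_seq(3000, 300 + i) + unit * (4000 // period + 1) \
            + _rand_seq(3000, 400 + i)
        calls = R.detect_tandem_monomer(seq)
        assert [c.period for c in calls] == [period]


def test_monomer_default_sim_recovers_planted_arrays(default_sim):
    mono = R.find_monomers(default_sim.genome)
    truth = default_sim.truth.centromeres
    assert len(mono) == len(truth)
    assert (mono["period"] == 147).all()
    merged = mono.merge(truth, on="chrom", suffixes=("", "_t"))
    overlap = (np.minimum(merged["stop"], merged["stop_t"])
               - np.maximum(merged["start"], merged["start_t"]))
    assert (overlap >= 0.95 * (truth["stop"] - truth["start"]).iloc[0]).all()


# ---------------------------------------------------------------------------
# composition


def _fs(rows):
    return pio.FeatureSet(pd.DataFrame(rows))


def test_composition_single_te_fraction():
    g = pio.Genome({"chr_1A": "A" * 1000})
    tes = _fs([{"chrom": "chr_1A", "start": 100, "end": 200,
                "classification": "LTR/Gypsy"}])
    comp = R.te_composition(tes, g)
    assert comp.loc[0, "LTR/Gypsy"] == pytest.approx(0.10)
    assert comp.loc[0, "total_fraction"] == pytest.approx(0.10)


def test_composition_merges_overlaps():
    g = pio.Genome({"chr_1A": "A" * 1000})
    tes = _fs([
        {"chrom": "chr_1A", "start": 0, "end": 100, "classification": "LTR/Gypsy"},
        {"chrom": "chr_1A", "start": 50, "end": 150, "classification": "LTR/Gypsy"},
    ])
    comp = R.te_composition(tes, g)
    assert comp.loc[0, "LTR/Gypsy"] == pytest.approx(0.15)  # merged, not 0.20


def test_composition_unlabeled_goes_to_unassigned():
    g = pio.Genome({"scaffoldX": "A" * 1000})
    tes = _fs([{"chrom": "scaffoldX", "start": 0, "end": 10,
                "classification": "DNA"}])
    comp = R.te_composition(tes, g)
    assert comp["subgenome"].tolist() == ["unassigned"]


def test_composition_subgenome_ordering(default_sim):
    """A carries the lightest TE load; B, C, D are equivalent."""
    comp = R.te_composition(default_sim.tes, default_sim.genome).set_index("subgenome")
    a = comp.loc["A", "total_fraction"]
    bcd = comp.loc[["B", "C", "D"], "total_fraction"]
    assert a < bcd.min()
    assert bcd.max() / bcd.min() < 1.1
    assert comp[["LTR/Copia", "LTR/Gypsy", "LINE", "DNA", "Simple"]].notna().all().all()


def test_composition_fractions_bounded(default_sim):
    comp = R.te_composition(default_sim.tes, default_sim.genome)
    cls = ["LTR/Copia", "LTR/Gypsy", "LINE", "DNA", "Simple"]
    assert ((comp[cls] >= 0) & (comp[cls] <= 1)).all().all()
    assert (comp[cls].sum(axis=1) <= 1 + 1e-12).all()
    assert ((comp["total_fraction"] >= 0) & (comp["total_fraction"] <= 1)).all()


# ---------------------------------------------------------------------------
# distances / intragenic labels


def test_gene_te_distance_example():
    genes = _fs([{"chrom": "chr_1A", "start": 1000, "end": 2000, "id": "g1"}])
    tes = _fs([{"chrom": "chr_1A", "start": 100, "end": 200},
               {"chrom": "chr_1A", "start": 2300, "end": 2500}])
    per_gene, _ = R.gene_te_distance(genes, tes)
    assert per_gene.loc[0, "distance"] == 300


def test_gene_te_distance_overlap_zero():
    genes = _fs([{"chrom": "chr_1A", "start": 1000, "end": 2000, "id": "g1"}])
    tes = _fs([{"chrom": "chr_1A", "start": 1999, "end": 2500}])
    per_gene, _ = R.gene_te_distance(genes, tes)
    assert per_gene.loc[0, "distance"] == 0


def test_gene_te_distance_no_te_chromosome_undefined():
    genes = _fs([{"chrom": "chr_1A", "start": 10, "end": 20, "id": "g1"}])
    tes = _fs([{"chrom": "chr_2A", "start": 0, "end": 5}])
    per_gene, summary = R.gene_te_distance(genes, tes)
    assert np.isnan(per_gene.loc[0, "distance"])
    assert summary.loc[0, "n_undefined"] == 1
    assert np.isnan(summary.loc[0, "fraction_within_cutoff"])


def _brute_distance(gene, tes):
    gs, ge = gene
    best = None
    for ts, te in tes:
        if ts < ge and te > gs:
            return 0
        d = ts - ge if ts >= ge else gs - te
        best = d if best is None else min(best, d)
    return best


def test_distance_and_position_match_bruteforce_on_random_instances():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n_genes, n_tes = rng.integers(1, 8), rng.integers(1, 12)
        gene_rows, te_rows = [], []
        gene_ivs, te_ivs = [], []
        for i in range(n_genes):
            s = int(rng.integers(0, 9000)); e = s + int(rng.integers(1, 800))
            gene_rows.append({"chrom": "chr_1A", "start": s, "end": e,
                              "id": f"g{i}"})
            gene_ivs.append((s, e))
        for i in range(n_tes):
            s = int(rng.integers(0, 9000)); e = s + int(rng.integers(1, 800))
            te_rows.append({"chrom": "chr_1A", "start": s, "end": e,
                            "id": f"t{i}"})
            te_ivs.append((s, e))
        genes, tes = _fs(gene_rows), _fs(te_rows)
        per_gene, _ = R.gene_te_distance(genes, tes)
        for i, (gs, ge) in enumerate(gene_ivs):
            assert per_gene.loc[i, "distance"] == _brute_distance((gs, ge), te_ivs)
        labels = R.classify_te_position(genes, tes)
        for i, (ts, te) in enumerate(te_ivs):
            expected = any(ts < ge and te > gs for gs, ge in gene_ivs)
            assert (labels.loc[i, "position_class"] == "intragenic") == expected


def test_te_position_boundary_rules():
    genes = _fs([{"chrom": "chr_1A", "start": 100, "end": 200, "id": "g"}])
    inside = _fs([{"chrom": "chr_1A", "start": 120, "end": 150, "id": "t"}])
    outside = _fs([{"chrom": "chr_1A", "start": 200, "end": 300, "id": "t"}])
    touching = _fs([{"chrom": "chr_1A", "start": 199, "end": 300, "id": "t"}])
    assert R.classify_te_position(genes, inside)["position_class"][0] == "intragenic"
    assert R.classify_te_position(genes, outside)["position_class"][0] == "intergenic"
    assert R.classify_te_position(genes, touching)["position_class"][0] == "intragenic"


def test_distance_symmetric_for_single_intervals():
    rng = np.random.default_rng(10)
    for _ in range(100):
        s1 = int(rng.integers(0, 5000)); e1 = s1 + int(rng.integers(1, 500))
        s2 = int(rng.integers(0, 5000)); e2 = s2 + int(rng.integers(1, 500))
        f1 = _fs([{"chrom": "chr_1A", "start": s1, "end": e1, "id": "a"}])
        f2 = _fs([{"chrom": "chr_1A", "start": s2, "end": e2, "id": "b"}])
        d12, _ = R.gene_te_distance(f1, f2)
        d21, _ = R.gene_te_distance(f2, f1)
        assert d12.loc[0, "distance"] == d21.loc[0, "distance"]


# ---------------------------------------------------------------------------
# LTR dating


def test_identical_ltrs_time_zero():
    pairs = pd.DataFrame([{"te_id": "t", "subgenome": "A",
                           "ltr5": "ACGT" * 50, "ltr3": "ACGT" * 50}])
    dated, _ = R.ltr_insertion_time(pairs)
    assert dated.loc[0, ["p", "K", "T"]].tolist() == [0.0, 0.0, 0.0]


def test_analytic_insertion_time():
    # K = 0.026 at mu = 1.3e-8 -> one million years (to float precision)
    assert R.insertion_time(0.026, mu=1.3e-8) == pytest.approx(1.0e6, rel=1e-12)


def test_jc_correction_bounds():
    p = np.linspace(0.0, 0.7, 50)
    K = R.jc_correct(p)
    assert (K >= p - 1e-15).all()
    assert abs(R.jc_correct(1e-4) - 1e-4) < 1e-6  # K -> p as p -> 0


def test_saturated_pairs_flagged_and_excluded():
    a = "A" * 100
    b = "C" * 100  # p = 1 >= 0.75
    pairs = pd.DataFrame([
        {"te_id": "sat", "subgenome": "A", "ltr5": a, "ltr3": b},
        {"te_id": "ok", "subgenome": "A", "ltr5": a, "ltr3": a},
    ])
    dated, summ = R.ltr_insertion_time(pairs)
    assert dated.set_index("te_id").loc["sat", "saturated"]
    assert summ.loc[0, "n"] == 1


def test_n_sites_skipped():
    pairs = pd.DataFrame([{"te_id": "t", "subgenome": "A",
                           "ltr5": "ACGTN" * 20, "ltr3": "ACGTA" * 20}])
    dated, _ = R.ltr_insertion_time(pairs)
    assert dated.loc[0, "p"] == 0.0  # mismatching N column skipped


def test_unequal_ltr_lengths_rejected():
    pairs = pd.DataFrame([{"te_id": "t", "subgenome": "A",
                           "ltr5": "ACGT", "ltr3": "ACGTA"}])
    with pytest.raises(ValueError, match="unequal"):
        R.ltr_insertion_time(pairs)


def test_planted_divergence_recovery_median_within_ten_percent():
    rng = np.random.default_rng(11)
    d = 0.052
    rows = []
    for i in range(500):
        ltr5 = rng.integers(0, 4, 300, dtype=np.uint8)
        rows.append({"te_id": f"t{i}", "subgenome": "A",
                     "ltr5": decode(ltr5), "ltr3": decode(mutate(ltr5, d, rng))})
    dated, _ = R.ltr_insertion_time(pd.DataFrame(rows))
    expected = R.insertion_time(R.jc_correct(d))
    assert abs(np.median(dated["T"]) - expected) / expected < 0.10


def test_extract_ltr_pairs_matches_truth(default_sim):
    pairs = R.extract_ltr_pairs(default_sim.tes, default_sim.genome)
    truth = default_sim.truth.ltr_pairs
    assert set(pairs["te_id"]) == set(truth["te_id"])
    dated, summ = R.ltr_insertion_time(pairs)
    expected = R.insertion_time(R.jc_correct(default_sim.config.ltr_divergence))
    assert abs(np.median(dated["T"]) - expected) / expected < 0.10
    assert set(summ["subgenome"]) == {"A", "B", "C", "D"}
    assert (summ["ci_low"] <= summ["median_T"]).all()
    assert (summ["median_T"] <= summ["ci_high"]).all()
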