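"""Synthetic allopolyploid data generator.

Generates a small allopolyploid genome with the statistical structure the
downstream stages assume: one ancestral sequence per homoeologous group
evolved along a rooted progenitor topology (default ``(A,(B,(C,D)))``);
TE families that also descend along that topology, each leaf copy carrying a
leaf-private 31-bp seed motif so subgenome-diagnostic 15-mers provably
exist; LTR elements whose twin LTRs are diverged by a planted rate (dating
signal); telomeric ``(TTTAGGG)n`` arrays; a centromeric tandem monomer
array; single-exon CDS genes with homeolog pairs across subgenomes and an
outgroup copy; a beta-binomially sampled methylome with planted
gene-body-methylated (gbM) genes; and homeolog count pairs with planted
expression-bias fractions.

Every emitted feature appears in exactly one truth row, and identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import io as pio
from ._seq import encode, decode, revcomp, random_codes, mutate

TELOMERE_MOTIF = "TTTAGGG"
MOTIF_LEN = 31  # family-private seed motif; > 2*15 - 1 so its 15-mers are unambiguous


class CapacityError(ValueError):
    """Planted features do not fit on a chromosome."""


# ---------------------------------------------------------------------------
# configuration


def _default_meth_levels():
    return {
        "background": {"CG": 0.10, "CHG": 0.05, "CHH": 0.02},
        "gbm": {"CG": 0.60, "CHG": 0.05, "CHH": 0.02},
        "te": {"CG": 0.85, "CHG": 0.65, "CHH": 0.30},
    }


@dataclass
class SimConfig:
    """All tunable parameters of the generator (defaults are the study
    conditions exercised by the test-suite)."""

    seed: int = 0
    n_groups: int = 7
    subgenomes: tuple = ("A", "B", "C", "D")
    chrom_len: int = 300_000
    topology: str = "(A:4,(B:0.6,(C:0.5,D:0.5):0.15):3);"
    branch_sub_rate: float = 0.02  # substitutions/site per unit branch length
    te_families_per_subgenome: int = 2
    te_family_divergence: float = 0.03  # family backbone, per unit branch length
    te_len: int = 3000
    ltr_len: int = 300
    ltr_divergence: float = 0.052  # planted between 5'/3' LTR copies
    te_copies_per_chrom: int = 8  # per family, before te_load scaling
    te_copy_divergence: float = 0.01  # per-copy drift from the family consensus
    te_load: dict | None = None  # subgenome -> copy-number multiplier
    telomere_copies: int = 30
    telomere_missing: int = 0  # number of chromosome ends left without an array
    monomer_len: int = 147
    monomer_copies: int = 100
    monomer_copy_divergence: float = 0.005
    n_genes_per_chrom: int = 30
    gene_len: int = 600  # bases, multiple of 3 (single-exon CDS)
    omega: dict | None = None  # subgenome -> nonsynonymous acceptance probability
    omega_internal: float = 0.5
    outgroup_branch_len: float = 3.0
    gbm_fraction: float = 0.3
    meth_levels: dict = field(default_factory=_default_meth_levels)
    meth_overdispersion: float = 0.1  # beta-binomial rho
    read_depth: float = 30.0
    low_coverage_fraction: float = 0.02  # sites re-drawn at ~Poisson(0.7) depth
    n_pairs: int = 2000
    n_replicates: int = 2
    bias_fraction_A: float = 0.52
    bias_fraction_X: float | None = None  # default: 1 - bias_fraction_A
    bias_effect: float = 2.0
    gbm_bias_coupling: float = 0.0  # P(favored copy is the gbM one | states differ)
    count_mean: float = 200.0
    count_sigma: float = 0.8  # lognormal spread of per-anchor expression
    count_dispersion: float = 0.1  # NB dispersion (shared biological factor)

    def __post_init__(self):
        if self.te_load is None:
            self.te_load = {s: (0.5 if i == 0 else 1.0) for i, s in enumerate(self.subgenomes)}
        if self.omega is None:
            self.omega = {s: (0.15 if i == 0 else 0.5) for i, s in enumerate(self.subgenomes)}
        for name in ("branch_sub_rate", "ltr_divergence", "te_family_divergence",
                     "te_copy_divergence", "monomer_copy_divergence"):
            v = getattr(self, name)
            if not (0 <= v < 0.75):
                raise ValueError(f"{name}={v} outside [0, 0.75)")
        for name in ("gbm_fraction", "bias_fraction_A", "low_coverage_fraction",
                     "gbm_bias_coupling"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.bias_fraction_X is not None and not (
            0 <= self.bias_fraction_X <= 1 - self.bias_fraction_A + 1e-12
        ):
            raise ValueError("bias_fraction_A + bias_fraction_X must be <= 1")
        if self.gene_len % 3:
            raise ValueError("gene_len must be a multiple of 3")
        if self.te_len < 2 * self.ltr_len + 3 * MOTIF_LEN:
            raise ValueError("te_len too short for two LTRs plus seed motifs")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "subgenomes" in data:
            data["subgenomes"] = tuple(data["subgenomes"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["subgenomes"] = list(self.subgenomes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# tree handling


def parse_topology(newick: str, leaves_expected) -> TreeNode:
    tree = TreeNode.read(_stdio.StringIO(newick))
    names = sorted(t.name for t in tree.tips())
    if names != sorted(leaves_expected):
        raise ValueError(
            f"topology leaves {names} do not match subgenomes {list(leaves_expected)}"
        )
    return tree


def _evolve_along_tree(anc, tree, rate_per_unit, rng, mutate_fn=None):
    """Evolve ``anc`` down every branch; returns leaf-name -> codes.

    Mutations on shared internal branches are shared by all descendants,
    which is what makes closely related subgenomes correlated.
    """
    if mutate_fn is None:
        mutate_fn = lambda codes, rate, rng, edge=None: mutate(codes, rate, rng)
    out = {}

    def rec(node, codes):
        for child in node.children:
            bl = child.length if child.length is not None else 1.0
            evolved = mutate_fn(codes, rate_per_unit * bl, rng,
                                edge=child.name if child.is_tip() else None)
            if child.is_tip():
                out[child.name] = evolved
            else:
                rec(child, evolved)

    rec(tree, anc)
    return out


# ---------------------------------------------------------------------------
# codon-aware evolution

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _codon_aa_table() -> np.ndarray:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    aa = np.empty(64, dtype="U1")
    bases = "ACGT"
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            for k, c in enumerate(bases):
                codon = a + b + c
                idx = 16 * i + 4 * j + k
                aa[idx] = "*" if codon in _STOP_CODONS else table.forward_table[codon]
    return aa


_AA = _codon_aa_table()


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """ATG followed by random non-stop codons (no terminal stop)."""
    sense = np.nonzero(_AA != "*")[0]
    codons = sense[rng.integers(0, sense.size, n_codons - 1)]
    out = np.empty(3 * n_codons, dtype=np.uint8)
    out[0], out[1], out[2] = 0, 3, 2  # ATG
    for i, cod in enumerate(codons):
        base = 3 * (i + 1)
        out[base] = (cod >> 4) & 3
        out[base + 1] = (cod >> 2) & 3
        out[base + 2] = cod & 3
    return out


def mutate_cds(codes: np.ndarray, rate: float, omega: float,
               rng: np.random.Generator) -> np.ndarray:
    """Propose i.i.d. substitutions; reject stops; accept nonsynonymous
    changes with probability ``omega`` (purifying selection knob)."""
    out = codes.copy()
    if rate <= 0:
        return out
    pos = np.nonzero(rng.random(out.size) < rate)[0]
    for i in pos:
        new_base = (out[i] + rng.integers(1, 4)) % 4
        ci = i - i % 3
        old_idx = 16 * out[ci] + 4 * out[ci + 1] + out[ci + 2]
        tmp = out[ci : ci + 3].copy()
        tmp[i - ci] = new_base
        new_idx = 16 * tmp[0] + 4 * tmp[1] + tmp[2]
        if _AA[new_idx] == "*":
            continue
        if _AA[new_idx] != _AA[old_idx] and rng.random() >= omega:
            continue
        out[i] = new_base
    return out


# ---------------------------------------------------------------------------
# truth tables


@dataclass
class TruthTables:
    chroms: pd.DataFrame
    genes: pd.DataFrame
    telomeres: pd.DataFrame
    centromeres: pd.DataFrame
    ltr_pairs: pd.DataFrame
    pairs: pd.DataFrame
    gbm: pd.DataFrame | None = None
    bias: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        for name in ("chroms", "genes", "telomeres", "centromeres",
                     "ltr_pairs", "pairs", "gbm", "bias"):
            df = getattr(self, name)
            if df is not None:
                pio.write_table(df, outdir / f"truth_{name}.tsv")


@dataclass
class SimulatedGenome:
    config: SimConfig
    genome: pio.Genome
    genes: pio.FeatureSet
    tes: pio.FeatureSet
    cds: dict[str, str]  # gene id -> coding-strand CDS
    outgroup_cds: dict[str, str]  # anchor id -> outgroup CDS
    pairs: pd.DataFrame  # pair_id, anchor, gene_a, gene_x, x
    truth: TruthTables


# ---------------------------------------------------------------------------
# TE library


def _build_te_library(config: SimConfig, tree: TreeNode):
    """Family catalogue. Diagnostic LTR families descend along the topology
    and carry a leaf-private seed motif; LINE/DNA/Simple families are shared
    verbatim across subgenomes (non-diagnostic)."""
    rng = _rng(config.seed, 1)
    families = []  # dicts: family_id, classification, per-leaf element parts
    nfam = config.te_families_per_subgenome
    internal_len = config.te_len - 2 * config.ltr_len
    for r in range(nfam):
        cls = "LTR/Copia" if r % 2 == 0 else "LTR/Gypsy"
        anc_ltr = random_codes(config.ltr_len, rng)
        anc_int = random_codes(internal_len, rng)
        leaf_ltr = _evolve_along_tree(anc_ltr, tree, config.te_family_divergence, rng)
        leaf_int = _evolve_along_tree(anc_int, tree, config.te_family_divergence, rng)
        per_leaf = {}
        for sub in config.subgenomes:
            motif = random_codes(MOTIF_LEN, rng)
            internal = leaf_int[sub].copy()
            # three tandem-spaced copies of the leaf-private seed motif
            step = max(MOTIF_LEN, (internal_len - 100) // 3)
            offsets = [50 + i * step for i in range(3) if 50 + i * step + MOTIF_LEN <= internal_len]
            for off in offsets:
                internal[off : off + MOTIF_LEN] = motif
            per_leaf[sub] = {"ltr": leaf_ltr[sub], "internal": internal, "motif": motif}
        families.append(
            {"family_id": f"fam{r}", "classification": cls, "ltr": True,
             "per_leaf": per_leaf}
        )
    shared_specs = [("LINE_sh0", "LINE", 1500, 3), ("DNA_sh0", "DNA", 800, 3)]
    for fid, cls, length, copies in shared_specs:
        seq = random_codes(length, rng)
        families.append(
            {"family_id": fid, "classification": cls, "ltr": False,
             "consensus": seq, "copies": copies}
        )
    simple_unit = random_codes(5, rng)
    families.append(
        {"family_id": "SIMPLE_sh0", "classification": "Simple", "ltr": False,
         "consensus": np.tile(simple_unit, 100), "copies": 2}
    )
    return families


# ---------------------------------------------------------------------------
# placement helpers


def _place_in_gaps(gaps: list[list[int]], length: int, rng) -> int | None:
    """Pick a position of ``length`` bases inside one of the free gaps
    (weighted by usable length) and split that gap.  Returns the start."""
    usable = [(i, g[1] - g[0] - length) for i, g in enumerate(gaps)
              if g[1] - g[0] >= length]
    if not usable:
        return None
    weights = np.array([u[1] + 1 for u in usable], dtype=float)
    pick = usable[rng.choice(len(usable), p=weights / weights.sum())]
    gi, avail = pick
    start, end = gaps[gi]
    pos = start + int(rng.integers(0, avail + 1))
    gaps[gi] = [start, pos]
    gaps.insert(gi + 1, [pos + length, end])
    gaps[:] = [g for g in gaps if g[1] - g[0] > 0]
    return pos


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    tree = parse_topology(config.topology, config.subgenomes)
    families = _build_te_library(config, tree)
    L = config.chrom_len
    telo_len = len(TELOMERE_MOTIF) * config.telomere_copies
    cen_len = config.monomer_len * config.monomer_copies
    cen_start = L // 2 - cen_len // 2
    cen_end = cen_start + cen_len
    margin = 200

    # capacity pre-check per subgenome (TE load differs)
    for sub in config.subgenomes:
        te_bases = 0
        for fam in families:
            if fam["ltr"]:
                copies = max(0, round(config.te_copies_per_chrom * config.te_load[sub]))
                te_bases += copies * config.te_len
            else:
                te_bases += fam["copies"] * len(fam["consensus"])
        need = (2 * telo_len + cen_len + config.n_genes_per_chrom * (config.gene_len + margin)
                + te_bases + 4 * margin)
        if need > L:
            raise CapacityError(
                f"chromosome chr_*{sub}: planted features need ~{need} bases "
                f"but chrom_len is {L}"
            )

    # which telomere ends are left un-planted (scenario knob)
    all_ends = [(f"chr_{g}{s}", e) for g in range(1, config.n_groups + 1)
                for s in config.subgenomes for e in ("5p", "3p")]
    rng_tel = _rng(config.seed, 2)
    missing = set()
    if config.telomere_missing:
        idx = rng_tel.choice(len(all_ends), size=config.telomere_missing, replace=False)
        missing = {all_ends[i] for i in idx}

    monomer = random_codes(config.monomer_len, _rng(config.seed, 4))

    chroms: dict[str, str] = {}
    gene_rows, te_rows = [], []
    tel_rows, cen_rows, ltr_rows, pair_rows = [], [], [], []
    cds_store: dict[str, str] = {}
    outgroup: dict[str, str] = {}
    chrom_rows = []

    telo5 = encode(TELOMERE_MOTIF * config.telomere_copies)
    telo3 = encode(revcomp(TELOMERE_MOTIF) * config.telomere_copies)

    for g in range(1, config.n_groups + 1):
        rng_g = _rng(config.seed, 3, g)
        backbone_anc = random_codes(L, rng_g)
        backbones = _evolve_along_tree(backbone_anc, tree, config.branch_sub_rate, rng_g)

        # gene slots shared across the group's subgenomes
        arms = [
            (telo_len + margin, cen_start - margin),
            (cen_end + margin, L - telo_len - margin),
        ]
        arm_lens = [max(0, b - a) for a, b in arms]
        n_genes = config.n_genes_per_chrom
        n_arm0 = round(n_genes * arm_lens[0] / max(1, sum(arm_lens)))
        slots, strands = [], []
        for arm_i, n_arm in enumerate((n_arm0, n_genes - n_arm0)):
            a, b = arms[arm_i]
            if n_arm == 0:
                continue
            spacing = (b - a) // n_arm
            if spacing < config.gene_len + margin:
                raise CapacityError(
                    f"chromosome chr_{g}*: {n_genes} genes of {config.gene_len} bp "
                    f"do not fit between telomeres and centromere"
                )
            for i in range(n_arm):
                jitter = int(rng_g.integers(0, spacing - config.gene_len + 1))
                slots.append(a + i * spacing + jitter)
                strands.append("+" if rng_g.random() < 0.5 else "-")

        # ancestral CDS per anchor, evolved along the topology and an outgroup branch
        anchors = []
        for i in range(n_genes):
            anc_cds = random_cds(config.gene_len // 3, rng_g)
            leaves = _evolve_along_tree(
                anc_cds, tree, config.branch_sub_rate, rng_g,
                mutate_fn=lambda codes, rate, rng, edge=None: mutate_cds(
                    codes, rate,
                    config.omega[edge] if edge is not None else config.omega_internal,
                    rng,
                ),
            )
            out_cds = mutate_cds(
                anc_cds, config.branch_sub_rate * config.outgroup_branch_len,
                config.omega_internal, rng_g,
            )
            anchor = f"g{g}_{i:03d}"
            anchors.append((anchor, leaves))
            outgroup[anchor] = decode(out_cds)

        for sub in config.subgenomes:
            chrom = f"chr_{g}{sub}"
            rng_c = _rng(config.seed, 5, g, list(config.subgenomes).index(sub))
            seq = backbones[sub].copy()
            chrom_rows.append({"chrom": chrom, "group": g, "subgenome": sub})

            # telomeres
            if (chrom, "5p") not in missing:
                seq[:telo_len] = telo5
                tel_rows.append({"chrom": chrom, "end": "5p", "start": 0,
                                 "stop": telo_len, "copies": config.telomere_copies})
            if (chrom, "3p") not in missing:
                seq[L - telo_len :] = telo3
                tel_rows.append({"chrom": chrom, "end": "3p", "start": L - telo_len,
                                 "stop": L, "copies": config.telomere_copies})

            # centromeric monomer array
            array = np.concatenate([
                mutate(monomer, config.monomer_copy_divergence, rng_c)
                for _ in range(config.monomer_copies)
            ])
            seq[cen_start:cen_end] = array
            cen_rows.append({"chrom": chrom, "start": cen_start, "stop": cen_end,
                             "period": config.monomer_len,
                             "copies": config.monomer_copies})

            # genes
            occupied = []
            for (anchor, leaves), slot, strand in zip(anchors, slots, strands):
                gid = f"{anchor}_{sub}"
                cds = leaves[sub]
                cds_store[gid] = decode(cds)
                insert = cds if strand == "+" else encode(revcomp(decode(cds)))
                seq[slot : slot + config.gene_len] = insert
                occupied.append((slot, slot + config.gene_len))
                gene_rows.append({
                    "chrom": chrom, "start": slot, "end": slot + config.gene_len,
                    "strand": strand, "id": gid, "type": "gene",
                    "classification": "",
                    "attributes": f"ID={gid};anchor={anchor}",
                })

            # free gaps for TE placement
            blocked = sorted([(0, telo_len), (cen_start, cen_end), (L - telo_len, L)]
                             + occupied)
            gaps, cursor = [], 0
            for a, b in blocked:
                if a > cursor:
                    gaps.append([cursor, a])
                cursor = max(cursor, b)
            if cursor < L:
                gaps.append([cursor, L])

            te_i = 0
            for fam in families:
                if fam["ltr"]:
                    copies = max(0, round(config.te_copies_per_chrom * config.te_load[sub]))
                    parts = fam["per_leaf"][sub]
                    for _ in range(copies):
                        ltr5 = mutate(parts["ltr"], config.te_copy_divergence, rng_c)
                        internal = mutate(parts["internal"], config.te_copy_divergence, rng_c)
                        ltr3 = mutate(ltr5, config.ltr_divergence, rng_c)
                        element = np.concatenate([ltr5, internal, ltr3])
                        pos = _place_in_gaps(gaps, element.size, rng_c)
                        if pos is None:
                            raise CapacityError(
                                f"chromosome {chrom}: no room left for TE copies"
                            )
                        seq[pos : pos + element.size] = element
                        te_id = f"{chrom}_{fam['family_id']}_{te_i}"
                        te_i += 1
                        te_rows.append({
                            "chrom": chrom, "start": pos, "end": pos + element.size,
                            "strand": ".", "id": te_id, "type": "transposable_element",
                            "classification": fam["classification"],
                            "attributes": (
                                f"ID={te_id};Classification={fam['classification']};"
                                f"family={fam['family_id']};ltr_len={config.ltr_len}"
                            ),
                        })
                        ltr_rows.append({
                            "te_id": te_id, "chrom": chrom, "start": pos,
                            "end": pos + element.size, "subgenome": sub,
                            "ltr_len": config.ltr_len,
                            "planted_divergence": config.ltr_divergence,
                        })
                else:
                    for _ in range(fam["copies"]):
                        element = mutate(fam["consensus"], config.te_copy_divergence, rng_c)
                        pos = _place_in_gaps(gaps, element.size, rng_c)
                        if pos is None:
                            raise CapacityError(
                                f"chromosome {chrom}: no room left for TE copies"
                            )
                        seq[pos : pos + element.size] = element
                        te_id = f"{chrom}_{fam['family_id']}_{te_i}"
                        te_i += 1
                        te_rows.append({
                            "chrom": chrom, "start": pos, "end": pos + element.size,
                            "strand": ".", "id": te_id, "type": "transposable_element",
                            "classification": fam["classification"],
                            "attributes": (
                                f"ID={te_id};Classification={fam['classification']};"
                                f"family={fam['family_id']}"
                            ),
                        })

            chroms[chrom] = decode(seq)

        # homeolog pairs (subgenome A anchor vs each other subgenome)
        ref = config.subgenomes[0]
        for anchor, _ in anchors:
            for x in config.subgenomes[1:]:
                pair_rows.append({
                    "pair_id": f"{anchor}:{x}", "anchor": anchor,
                    "gene_a": f"{anchor}_{ref}", "gene_x": f"{anchor}_{x}", "x": x,
                })

    genome = pio.Genome(chroms)
    genes = pio.FeatureSet(pd.DataFrame(gene_rows), genome=genome)
    tes = pio.FeatureSet(pd.DataFrame(te_rows), genome=genome)
    truth = TruthTables(
        chroms=pd.DataFrame(chrom_rows),
        genes=pd.DataFrame(gene_rows)[["id", "chrom", "start", "end", "strand"]],
        telomeres=pd.DataFrame(tel_rows),
        centromeres=pd.DataFrame(cen_rows),
        ltr_pairs=pd.DataFrame(ltr_rows),
        pairs=pd.DataFrame(pair_rows),
    )
    return SimulatedGenome(
        config=config, genome=genome, genes=genes, tes=tes, cds=cds_store,
        outgroup_cds=outgroup, pairs=truth.pairs.copy(), truth=truth,
    )


# ---------------------------------------------------------------------------
# methylome simulation


_B_ORD = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_methylome(genome: pio.Genome, genes: pio.FeatureSet,
                       tes: pio.FeatureSet, config: SimConfig,
                       seed: int | None = None):
    """Beta-binomial methylome over every cytosine on both strands.

    Site context comes from the reference trinucleotide; the mean level is
    that of the innermost containing feature class (TE > gbM gene body >
    background).  Returns ``(CytosineTable, gbm_truth)``.
    """
    rng = _rng(config.seed if seed is None else seed, 10)

    gene_ids = list(genes.df["id"])
    n_gbm = int(round(config.gbm_fraction * len(gene_ids)))
    order = rng.permutation(len(gene_ids))
    gbm_ids = {gene_ids[i] for i in order[:n_gbm]}
    gbm_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "planted": ["gbM" if gid in gbm_ids else "background" for gid in gene_ids],
    })

    if config.read_depth <= 0:
        empty = pd.DataFrame({
            "chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str), "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64), "context": pd.Series(dtype=str),
            "tri": pd.Series(dtype=str),
        })
        return pio.CytosineTable(empty), gbm_truth

    levels = config.meth_levels
    frames = []
    for chrom in genome.names:
        codes = encode(genome[chrom])
        Lc = codes.size
        cls = np.zeros(Lc, dtype=np.uint8)  # 0 background, 1 gbM body, 2 TE
        gsub = genes.df[genes.df["chrom"] == chrom]
        for r in gsub.itertuples():
            if r.id in gbm_ids:
                cls[r.start : r.end] = 1
        tsub = tes.df[tes.df["chrom"] == chrom]
        for r in tsub.itertuples():
            cls[r.start : r.end] = 2  # innermost: TEs override gene bodies

        for strand in "+-":
            if strand == "+":
                pos0 = np.nonzero(codes[: Lc - 2] == 1)[0]
                n1, n2 = codes[pos0 + 1], codes[pos0 + 2]
                is_cg = n1 == 2
                is_chg = (~is_cg) & (n2 == 2)
                valid = (n1 <= 3) & (n2 <= 3)
                tri_codes = np.stack([codes[pos0], n1, n2], axis=1)
            else:
                pos0 = np.nonzero(codes[2:] == 2)[0] + 2
                n1, n2 = codes[pos0 - 1], codes[pos0 - 2]
                is_cg = n1 == 1
                is_chg = (~is_cg) & (n2 == 1)
                valid = (n1 <= 3) & (n2 <= 3)
                # trinucleotide read 5'->3' on the minus strand
                tri_codes = np.stack(
                    [3 - codes[pos0], 3 - n1, 3 - n2], axis=1
                ).astype(np.uint8)
            pos0, is_cg, is_chg, tri_codes = (
                pos0[valid], is_cg[valid], is_chg[valid], tri_codes[valid],
            )
            n = pos0.size
            if n == 0:
                continue
            ctx = np.where(is_cg, "CG", np.where(is_chg, "CHG", "CHH"))
            site_cls = cls[pos0]
            mean = np.empty(n)
            for ci, cname in enumerate(("background", "gbm", "te")):
                sel = site_cls == ci
                if not sel.any():
                    continue
                lv = levels[cname]
                mean[sel] = np.where(
                    is_cg[sel], lv["CG"], np.where(is_chg[sel], lv["CHG"], lv["CHH"])
                )
            rho = config.meth_overdispersion
            if rho > 0:
                a = mean * (1 - rho) / rho
                b = (1 - mean) * (1 - rho) / rho
                theta = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
            else:
                theta = mean
            depth = rng.poisson(config.read_depth, n)
            low = rng.random(n) < config.low_coverage_fraction
            depth[low] = rng.poisson(0.7, int(low.sum()))
            n_meth = rng.binomial(depth, theta)
            tri = _B_ORD[tri_codes].view(f"S3").astype("U3").ravel()
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos0 + 1, "strand": strand,
                "n_meth": n_meth, "n_unmeth": depth - n_meth,
                "context": ctx, "tri": tri,
            }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    return pio.CytosineTable(df), gbm_truth


# ---------------------------------------------------------------------------
# counts simulation


def simulate_counts(pairs, config: SimConfig, gbm_truth: pd.DataFrame | None = None,
                    seed: int | None = None):
    """Homeolog pair counts with planted bias classes.

    Each (anchor, replicate) draws a shared Gamma biological factor that
    multiplies the expected value of *both* copies before Poisson sampling,
    so marginal counts are negative binomial while the pair total carries an
    exactly binomial null - see the methods note.  Returns
    ``(counts DataFrame, bias truth)``.
    """
    rng = _rng(config.seed if seed is None else seed, 11)
    if isinstance(pairs, (int, np.integer)):
        pairs = pd.DataFrame({
            "pair_id": [f"p{i:05d}:B" for i in range(pairs)],
            "anchor": [f"p{i:05d}" for i in range(pairs)],
            "gene_a": [f"p{i:05d}_A" for i in range(pairs)],
            "gene_x": [f"p{i:05d}_B" for i in range(pairs)],
            "x": "B",
        })
    pairs = pairs.reset_index(drop=True)
    n = len(pairs)
    if n < 1:
        raise ValueError("need at least one pair")

    fa = config.bias_fraction_A
    fx = (1 - fa) if config.bias_fraction_X is None else config.bias_fraction_X
    u = rng.random(n)
    cls = np.where(u < fa, "A", np.where(u < fa + fx, "X", "unbiased"))

    if gbm_truth is not None and config.gbm_bias_coupling > 0:
        state = dict(zip(gbm_truth["gene_id"], gbm_truth["planted"]))
        flip = rng.random(n) < config.gbm_bias_coupling
        for i in range(n):
            sa = state.get(pairs.at[i, "gene_a"]) == "gbM"
            sx = state.get(pairs.at[i, "gene_x"]) == "gbM"
            if flip[i] and sa != sx and cls[i] != "unbiased":
                cls[i] = "A" if sa else "X"

    anchors = pairs["anchor"].tolist()
    uniq_anchors = list(dict.fromkeys(anchors))
    base = dict(zip(
        uniq_anchors,
        rng.lognormal(np.log(config.count_mean), config.count_sigma, len(uniq_anchors)),
    ))

    phi = config.count_dispersion
    nrep = config.n_replicates
    lam = {}
    for anchor in uniq_anchors:
        if phi > 0:
            lam[anchor] = base[anchor] * rng.gamma(1 / phi, phi, nrep)
        else:
            lam[anchor] = np.full(nrep, base[anchor])

    eff = np.sqrt(config.bias_effect)
    genes, rows = [], []
    seen = set()
    for i in range(n):
        anchor = pairs.at[i, "anchor"]
        ga, gx = pairs.at[i, "gene_a"], pairs.at[i, "gene_x"]
        m_a = 1.0
        m_x = {"A": 1 / config.bias_effect, "X": config.bias_effect,
               "unbiased": 1.0}[cls[i]]
        if ga not in seen:
            seen.add(ga)
            genes.append(ga)
            rows.append(rng.poisson(lam[anchor] * m_a))
        if gx not in seen:
            seen.add(gx)
            genes.append(gx)
            rows.append(rng.poisson(lam[anchor] * m_x))
    counts = pd.DataFrame(
        np.vstack(rows), index=pd.Index(genes, name="gene_id"),
        columns=[f"rep{j + 1}" for j in range(nrep)],
    )
    truth = pairs[["pair_id", "gene_a", "gene_x", "x"]].copy()
    truth["planted"] = cls
    return counts, truth


# ---------------------------------------------------------------------------
# output writing


def write_outputs(sim: SimulatedGenome, outdir, cytosines=None, gbm_truth=None,
                  counts=None, bias_truth=None) -> None:
    """Write every external-interface file of the simulator."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_genome(sim.genome, outdir / "genome.fa")
    pio.write_features(sim.genes, outdir / "genes.gff3")
    pio.write_features(sim.tes, outdir / "tes.gff3")
    pio.write_table(sim.pairs, outdir / "pairs.tsv")
    _write_fasta_dict(sim.cds, outdir / "cds.fa")
    _write_fasta_dict(sim.outgroup_cds, outdir / "outgroup_cds.fa")
    truth = sim.truth
    if gbm_truth is not None:
        truth.gbm = gbm_truth
    if bias_truth is not None:
        truth.bias = bias_truth
    truth.write(outdir)
    if cytosines is not None:
        pio.write_cytosine_report(cytosines, outdir / "cytosines.tsv")
    if counts is not None:
        pio.write_counts(counts, outdir / "counts.tsv")


def _write_fasta_dict(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
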