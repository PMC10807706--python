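"""Readers and writers for the plain-text formats used across the pipeline.

Internal coordinate convention is 0-based, half-open everywhere; GFF3
(1-based, inclusive) and BED (0-based, half-open) are converted at the I/O
edge only.  Chromosome names of the form ``chr_<group><subgenome>`` (e.g.
``chr_1A``) carry a homoeologous-group number and a subgenome letter; other
names are accepted but left unlabeled, and subgenome-level operations reject
unlabeled input explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROM_PATTERN = re.compile(r"chr_(\d+)([A-Z])$")

VALID_BASES = set("ACGTN")
CONTEXTS = ("CG", "CHG", "CHH")


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_gff3_coords(self) -> tuple[int, int]:
        """Convert to GFF3 1-based inclusive (start, end)."""
        return self.start + 1, self.end

    @classmethod
    def from_gff3_coords(cls, chrom, start, end, strand=".") -> "GenomicInterval":
        return cls(chrom, int(start) - 1, int(end), strand)


# ---------------------------------------------------------------------------
# genome


class Genome:
    """Ordered chromosome-name -> sequence mapping with parsed labels.

    Sequences are uppercase strings over {A,C,G,T,N}.  ``labels`` maps each
    chromosome whose name matches ``pattern`` to ``(group, subgenome)``.
    """

    def __init__(self, chroms: dict[str, str], pattern: re.Pattern = CHROM_PATTERN):
        self.chroms: dict[str, str] = {}
        self.pattern = pattern
        self.labels: dict[str, tuple[int, str]] = {}
        for name, seq in chroms.items():
            if name in self.chroms:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            extra = set(seq) - VALID_BASES
            if extra:
                raise ValueError(
                    f"record {name!r} contains non-IUPAC characters {sorted(extra)}"
                )
            self.chroms[name] = seq
            m = pattern.match(name)
            if m:
                self.labels[name] = (int(m.group(1)), m.group(2))

    def __len__(self):
        return len(self.chroms)

    def __contains__(self, name):
        return name in self.chroms

    def __getitem__(self, name) -> str:
        return self.chroms[name]

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def group(self, name: str) -> int | None:
        lab = self.labels.get(name)
        return lab[0] if lab else None

    def subgenome(self, name: str) -> str | None:
        lab = self.labels.get(name)
        return lab[1] if lab else None

    def subgenomes(self) -> list[str]:
        return sorted({s for _, s in self.labels.values()})

    def groups(self) -> list[int]:
        return sorted({g for g, _ in self.labels.values()})

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.chroms[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            from ._seq import revcomp

            return revcomp(seq)
        return seq


def read_genome(path, pattern: re.Pattern = CHROM_PATTERN) -> Genome:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = str(rec.seq)
    return Genome(chroms, pattern=pattern)


def write_genome(genome: Genome, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# features


_GFF3_COLS = [
    "chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes",
]


def _parse_classification(cls: str) -> tuple[str, str]:
    if "/" in cls:
        order, superfam = cls.split("/", 1)
    else:
        order, superfam = cls, ""
    return order, superfam


class FeatureSet:
    """Set of genomic features as a DataFrame with internal coordinates.

    Columns: ``chrom, start, end, strand, id, type, classification,
    te_order, te_superfamily, attributes`` (classification columns empty for
    non-TE rows).  ``start``/``end`` are 0-based half-open.
    """

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.copy().reset_index(drop=True)
        for col, default in (
            ("strand", "."), ("id", ""), ("type", "feature"),
            ("classification", ""), ("attributes", ""),
        ):
            if col not in df.columns:
                df[col] = default
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(
                f"feature {bad['id']!r} has end <= start "
                f"({bad['chrom']}:{bad['start']}-{bad['end']})"
            )
        if genome is not None:
            unknown = set(df["chrom"]) - set(genome.names)
            if unknown:
                raise ValueError(f"features on unknown chromosomes: {sorted(unknown)}")
        parsed = df["classification"].map(_parse_classification)
        df["te_order"] = [p[0] for p in parsed]
        df["te_superfamily"] = [p[1] for p in parsed]
        self.df = df

    def __len__(self):
        return len(self.df)

    def subset(self, mask) -> "FeatureSet":
        return FeatureSet(self.df[mask])

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.df.itertuples()
        ]

    def attr(self, name: str) -> pd.Series:
        """Extract a ``key=value`` field from the raw attribute strings."""
        return self.df["attributes"].str.extract(rf"(?:^|;){name}=([^;]+)")[0]


def _attr_field(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return ""


def read_features(path, genome: Genome | None = None, fmt: str | None = None) -> FeatureSet:
    """Read GFF3 (1-based inclusive) or BED (0-based half-open) features.

    ``fmt`` is inferred from the extension when omitted.
    """
    path = str(path)
    if fmt is None:
        fmt = "bed" if path.endswith(".bed") else "gff3"
    if fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF3_COLS,
            dtype={"chrom": str}, na_filter=False,
        )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"].astype(int) - 1,
                "end": df["end"].astype(int),
                "strand": df["strand"],
                "id": [_attr_field(a, "ID") for a in df["attributes"]],
                "type": df["type"],
                "classification": [
                    _attr_field(a, "Classification") for a in df["attributes"]
                ],
                "attributes": df["attributes"],
            }
        )
    elif fmt == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, na_filter=False)
        names = ["chrom", "start", "end", "id", "score", "strand", "classification"]
        raw.columns = names[: raw.shape[1]]
        out = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "start": raw["start"].astype(int),
                "end": raw["end"].astype(int),
                "strand": raw["strand"] if "strand" in raw.columns else ".",
                "id": raw["id"] if "id" in raw.columns else "",
                "type": "feature",
                "classification": raw.get("classification", ""),
                "attributes": "",
            }
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return FeatureSet(out, genome=genome)


def write_features(features: FeatureSet, path, source: str = "polykit") -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    rows = []
    for r in features.df.itertuples():
        attrs = r.attributes
        if not attrs:
            attrs = f"ID={r.id}" if r.id else "."
            if r.classification:
                attrs += f";Classification={r.classification}"
        rows.append(
            "\t".join(
                [
                    r.chrom, source, r.type, str(int(r.start) + 1), str(int(r.end)),
                    ".", r.strand, ".", attrs,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(rows))
        if rows:
            fh.write("\n")


# ---------------------------------------------------------------------------
# cytosine report


_CX_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]


class CytosineTable:
    """Per-cytosine methylation calls.

    Columns: ``chrom, pos (1-based), strand, n_meth, n_unmeth, context, tri``.
    Coverage-0 rows are retained; filtering is an analysis-stage decision.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        if "tri" not in df.columns:
            df["tri"] = ""
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        bad = set(df["context"].unique()) - set(CONTEXTS)
        if bad:
            raise ValueError(f"unknown cytosine contexts: {sorted(bad)}")
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def coverage(self) -> pd.Series:
        return self.df["n_meth"] + self.df["n_unmeth"]


def read_cytosine_report(path) -> CytosineTable:
    df = pd.read_csv(
        path, sep="\t", header=None, names=_CX_COLS,
        dtype={
            "chrom": str, "pos": np.int64, "strand": str,
            "n_meth": np.int64, "n_unmeth": np.int64, "context": str, "tri": str,
        },
        na_filter=False,
    )
    return CytosineTable(df)


def write_cytosine_report(table: CytosineTable, path) -> None:
    table.df[_CX_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# counts and generic tables


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: gene_id column followed by one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df.set_index("gene_id")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_filter=True, keep_default_na=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
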