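"""Readers and writers for the standard formats the pipeline touches.

The pipeline consumes a genome (FASTA), a transcript annotation (GTF), known
SNP positions (VCF) and various tab-separated tables (read alignments,
pileups, junction counts, count matrices, result tables), plus a YAML run
configuration.  Coordinates are 1-based and intervals closed throughout,
matching pileup/VCF convention.
"""

from __future__ import annotations

import dataclasses
import os
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd
import yaml
from pyfaidx import Fasta

VALID_BASES = set("ACGTN")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class FormatError(ValueError):
    """Raised when an input file does not parse or validate."""


@dataclass
class GenomeRef:
    """Reference genome held in memory as chromosome -> sequence (ACGTN)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, b in enumerate(seq) if b in bad)
                raise FormatError(
                    f"chromosome {name!r} contains non-ACGTN base "
                    f"{seq[pos]!r} at position {pos + 1}"
                )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based closed; clipped to bounds."""
        seq = self.sequences[chrom]
        return seq[max(start - 1, 0): end]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # sorted, non-overlapping, closed
    cds: list[tuple[int, int]]            # subset of exon space; empty if ncRNA

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"transcript {self.tx_id}: overlapping exons "
                    f"({s1}-{e1}, {s2}-{e2})"
                )
        if self.cds:
            span = (self.exons[0][0], self.exons[-1][1])
            for s, e in self.cds:
                if s < span[0] or e > span[1]:
                    raise FormatError(
                        f"transcript {self.tx_id}: CDS {s}-{e} outside "
                        f"transcript span {span[0]}-{span[1]}"
                    )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def splice_boundaries(self) -> list[tuple[int, str]]:
        """Exon/intron boundaries as (last exonic position, side).

        For each adjacent exon pair the intron occupies
        (exon1.end+1 .. exon2.start-1); the boundary positions returned are
        the exonic positions flanking it, tagged with the direction of the
        intron relative to genomic coordinates.
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, "right"))   # intron extends to the right
            out.append((s2, "left"))    # intron extends to the left
        return out

    def region_of(self, pos: int) -> str | None:
        """Region class of a 1-based position, or None if outside the span."""
        lo, hi = self.span
        if pos < lo or pos > hi:
            return None
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            return "intron"
        if not self.cds:
            return "ncRNA"
        if any(s <= pos <= e for s, e in self.cds):
            return "CDS"
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        if pos < cds_lo:
            return "5'UTR" if self.strand == "+" else "3'UTR"
        if pos > cds_hi:
            return "3'UTR" if self.strand == "+" else "5'UTR"
        # exonic, inside CDS span but not in a CDS interval: should not occur
        # for well-formed models; treat as intron-like ambiguity
        return "intron"


@dataclass
class TranscriptModel:
    """Gene/transcript structure derived from a GTF annotation."""

    genes: pd.DataFrame                   # gene_id, chrom, start, end, strand
    transcripts: dict[str, Transcript]

    def __post_init__(self) -> None:
        self._by_gene: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            self._by_gene.setdefault(tx.gene_id, []).append(tx)
        # sorted gene interval index per chromosome for point lookup
        self._index: dict[str, tuple[list[int], list[tuple[int, str, str]]]] = {}
        for chrom, sub in self.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].tolist()
            rows = list(zip(sub["end"], sub["gene_id"], sub["strand"]))
            self._index[chrom] = (starts, rows)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return self._by_gene.get(gene_id, [])

    def genes_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """(gene_id, strand) of every gene whose span covers pos."""
        if chrom not in self._index:
            return []
        starts, rows = self._index[chrom]
        i = bisect_right(starts, pos)
        hits = []
        # genes may nest slightly; scan left while spans could still cover pos
        for j in range(i - 1, -1, -1):
            end, gid, strand = rows[j]
            if end >= pos:
                hits.append((gid, strand))
            elif pos - starts[j] > 10_000_000:
                break
        return hits

    def strand_at(self, chrom: str, pos: int) -> str | None:
        hits = self.genes_at(chrom, pos)
        return hits[0][1] if hits else None

    def splice_sites(self) -> list[tuple[str, int, str]]:
        """All (chrom, exonic boundary position, intron side) boundaries."""
        out = []
        for tx in self.transcripts.values():
            for pos, side in tx.splice_boundaries():
                out.append((tx.chrom, pos, side))
        return out

    def splice_proximal_positions(self, n_intronic: int = 4) -> set[tuple[str, int]]:
        """Positions 1..n_intronic nucleotides into the intron at each boundary."""
        out: set[tuple[str, int]] = set()
        for chrom, pos, side in self.splice_sites():
            if side == "right":
                out.update((chrom, pos + k) for k in range(1, n_intronic + 1))
            else:
                out.update((chrom, pos - k) for k in range(1, n_intronic + 1))
        return out

    def region_annotation(self, chrom: str, pos: int) -> tuple[str, bool]:
        """Consensus region class at a position and an ambiguity flag.

        Classes: CDS, 5'UTR, 3'UTR, intron, ncRNA, intergenic.  A position
        whose overlapping transcripts disagree is flagged ambiguous.
        """
        classes = set()
        for gid, _ in self.genes_at(chrom, pos):
            for tx in self.gene_transcripts(gid):
                r = tx.region_of(pos)
                if r is not None:
                    classes.add(r)
        if not classes:
            return "intergenic", False
        if len(classes) == 1:
            return classes.pop(), False
        return "ambiguous", True


@dataclass
class SnpSet:
    """Known variant positions to exclude from editing calls."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def read_genome(path: str | os.PathLike) -> GenomeRef:
    """Load a FASTA into memory, upper-casing bases and validating ACGTN."""
    try:
        fa = Fasta(str(path), read_long_names=False, rebuild=True)
    except Exception as exc:  # pyfaidx raises assorted classes
        raise FormatError(f"could not parse FASTA {path}: {exc}") from exc
    seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    # drop the index file pyfaidx writes alongside
    for ext in (".fai",):
        idx = str(path) + ext
        if os.path.exists(idx):
            try:
                os.remove(idx)
            except OSError:
                pass
    return GenomeRef(seqs)


def write_genome(genome: GenomeRef, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def _gtf_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | os.PathLike) -> TranscriptModel:
    """Parse a GTF with gene/transcript/exon/CDS features."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gene_rows = []
    for g in db.features_of_type("gene"):
        gene_rows.append(
            {
                "gene_id": g.attributes.get("gene_id", [g.id])[0],
                "chrom": g.seqid,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
        )
    transcripts: dict[str, Transcript] = {}
    for t in db.features_of_type("transcript"):
        tx_id = t.attributes.get("transcript_id", [t.id])[0]
        gene_id = t.attributes.get("gene_id", [tx_id])[0]
        exons = []
        cds = []
        for child in db.children(t, featuretype="exon"):
            exons.append((child.start, child.end))
        for child in db.children(t, featuretype="CDS"):
            cds.append((child.start, child.end))
        for s, e in exons:
            if s < t.start or e > t.end:
                raise FormatError(
                    f"transcript {tx_id}: exon {s}-{e} outside "
                    f"transcript span {t.start}-{t.end}"
                )
        transcripts[tx_id] = Transcript(tx_id, gene_id, t.seqid, t.strand, exons, cds)
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return TranscriptModel(genes, transcripts)


def write_annotation(model: TranscriptModel, path: str | os.PathLike) -> None:
    """Write a minimal GTF (gene/transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for _, g in model.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\teditome\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx in model.gene_transcripts(g.gene_id):
                lo, hi = tx.span
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx.tx_id}";'
                fh.write(
                    f"{g.chrom}\teditome\ttranscript\t{lo}\t{hi}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{g.chrom}\teditome\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )
                for s, e in tx.cds:
                    fh.write(
                        f"{g.chrom}\teditome\tCDS\t{s}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                    )


def read_snps(path: str | os.PathLike) -> SnpSet:
    """Collect unique (chrom, pos) from a VCF; multi-allelic lines count once."""
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise FormatError(f"could not parse VCF {path}: {exc}") from exc
    positions: set[tuple[str, int]] = set()
    with vf:
        for rec in vf:
            positions.add((rec.chrom, rec.pos))
    return SnpSet(positions)


def write_snps(snps: SnpSet, path: str | os.PathLike,
               ref_alt: dict[tuple[str, int], tuple[str, str]] | None = None) -> None:
    chroms = sorted({c for c, _ in snps.positions})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in sorted(snps.positions):
            ref, alt = (ref_alt or {}).get((chrom, pos), ("A", "G"))
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                strand_dialect: str = "symbol") -> None:
    """Write a result table as TSV with a deterministic column order.

    Floats are written at 6 significant digits.  ``strand_dialect`` controls
    how a ``strand`` column is encoded: ``"symbol"`` keeps "+"/"-";
    ``"numeric"`` writes 1 for the forward and 0 for the reverse strand.
    """
    df = df.copy()
    if strand_dialect == "numeric" and "strand" in df.columns:
        df["strand"] = df["strand"].map({"+": 1, "-": 0})
    elif strand_dialect not in ("symbol", "numeric"):
        raise ValueError(f"unknown strand dialect {strand_dialect!r}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "strand" in df.columns and df["strand"].dtype.kind in "if":
        df["strand"] = df["strand"].map({1: "+", 0: "-"})
    return df


@dataclass
class RunConfig:
    """A full pipeline run: file locations, thresholds, and the root seed.

    Threshold defaults follow the published analysis: editing-level floor
    0.02, coverage floor 10, edited-read floor 3, 4 nt intronic exclusion
    around splice sites, p <= 0.05 for differential editing, c = 6 clusters,
    dPSI >= 15 with range >= 5 for differential splicing, |log2FC| >= 1 with
    BH-adjusted p <= 0.05 for differential translational efficiency, and
    |r| >= 0.7 with p <= 0.05 for strong editing-splicing correlation.
    """

    outdir: str = "editome_run"
    seed: int = 0
    simulate: bool = True
    genome: str | None = None
    annotation: str | None = None
    snps: str | None = None
    reads: str | None = None
    junctions: str | None = None
    rna_counts: str | None = None
    ribo_counts: str | None = None

    trim_start: int = 12
    trim_end: int = 2
    min_el: float = 0.02
    min_coverage: int = 10
    min_edited: int = 3
    splice_intronic_nt: int = 4
    diffedit_p: float = 0.05
    n_clusters: int = 6
    min_dpsi: float = 15.0
    min_range: float = 5.0
    psi_min_ir: int = 25
    psi_min_other: int = 15
    psi_min_sample_frac: float = 0.2
    dte_min_log2fc: float = 1.0
    dte_max_padj: float = 0.05
    strong_r: float = 0.7
    corr_p: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.min_el <= 1:
            raise ValueError("min_el must be in [0, 1]")
        for name in ("min_coverage", "min_edited", "trim_start", "trim_end",
                     "splice_intronic_nt", "n_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("diffedit_p", "dte_max_padj", "corr_p",
                     "psi_min_sample_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.simulate:
            for name in ("genome", "annotation", "snps", "reads"):
                if getattr(self, name) is None:
                    raise ValueError(
                        f"config field {name!r} is required when simulate=false"
                    )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
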