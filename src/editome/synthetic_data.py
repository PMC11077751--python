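"""Synthetic retina-development editome with planted ground truth.

Generates a toy genome and multi-exon gene annotation, stranded read
alignments carrying temporally patterned A-to-I editing at planted sites
plus labelled contaminants, splice-event junction counts whose PSI
trajectories correlate with nearby editing, and negative-binomial RNA/Ribo
count matrices with planted translational-efficiency fold changes.

Every simulated record traces back to one row of the truth tables, so the
calling cascade, the differential tests, the clustering and the integration
analyses can all be scored against known answers.

Contaminant classes and the filter meant to remove each:

- ``snp``: genomic variant at a known-SNP position (mismatch fraction 0.5
  or 1.0) -> SNP filter;
- ``multiallelic``: two variant bases at one position -> multiallelic
  filter;
- ``low_support``: violates one of EL >= 0.02 / coverage >= 10 / edited
  >= 3 -> support filter;
- ``splice_proximal``: editing-like signal 1-4 nt into an intron from a
  splice boundary -> splice-proximity filter;
- ``read_end``: mismatches confined to the first 12 / last 2 nt of reads
  -> read-end trimming;
- ``single_rep``: signal in replicate 1 only -> both-replicates filter.

The simulator works at alignment-record granularity so the trimming filter
is exercised for real; a pileup fast path is derived from the same reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calling
from .io_formats import (
    COMPLEMENT,
    GenomeRef,
    SnpSet,
    Transcript,
    TranscriptModel,
)

TIMEPOINTS = ("E13", "P0", "P6", "P21", "P42")

# Six temporal editing-level trajectories: two rising after eye-opening
# (plateau and gradual) and four specific to a single time point.
DEFAULT_CLUSTER_PATTERNS = (
    (0.02, 0.05, 0.10, 0.50, 0.52),
    (0.03, 0.06, 0.12, 0.28, 0.55),
    (0.01, 0.45, 0.01, 0.01, 0.01),
    (0.01, 0.01, 0.45, 0.01, 0.01),
    (0.01, 0.01, 0.01, 0.45, 0.01),
    (0.01, 0.01, 0.01, 0.01, 0.45),
)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the study design (5 time points x 2 replicates) at a
    desk scale of 200 genes and 2,000 true editing sites, with per-replicate
    site coverage around 50 reads.
    """

    n_genes: int = 200
    n_true_sites: int = 2000
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_replicates: int = 2
    coverage_mean: float = 50.0
    read_length: int = 50
    trim_start: int = 12
    trim_end: int = 2
    cluster_patterns: tuple[tuple[float, ...], ...] = DEFAULT_CLUSTER_PATTERNS
    el_noise: float = 0.02
    motif_bias: float = 0.15        # G prob shift at -1 (down) and +1 (up)
    snp_rate: float = 0.04
    multiallelic_rate: float = 0.03
    low_support_rate: float = 0.04
    splice_proximal_rate: float = 0.02
    read_end_rate: float = 0.02
    single_rep_rate: float = 0.03
    seq_error_rate: float = 2e-4
    frac_es_genes: float = 0.6
    frac_as_genes: float = 0.65
    n_paired_sites: int = 240       # half positive, half negative correlation
    editing_splicing_rho: float = 0.95
    junction_coverage: float = 50.0
    n_unpaired_events: int = 120
    te_log2fc: float = 2.0
    n_dte_genes: int = 40
    nb_dispersion: float = 0.05
    count_mean: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        rates = (
            self.snp_rate, self.multiallelic_rate, self.low_support_rate,
            self.splice_proximal_rate, self.read_end_rate,
            self.single_rep_rate, self.seq_error_rate,
            self.frac_es_genes, self.frac_as_genes,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must be in [0, 1]")
        if abs(self.editing_splicing_rho) > 1:
            raise ValueError("|editing_splicing_rho| must be <= 1")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 time points")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for pat in self.cluster_patterns:
            if len(pat) != len(self.timepoints):
                raise ValueError("cluster patterns must span all time points")
            if any(not 0 <= v <= 1 for v in pat):
                raise ValueError("trajectory values must be in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return [
            f"{tp}_r{r + 1}"
            for tp in self.timepoints
            for r in range(self.n_replicates)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{tp}_r{r + 1}", "timepoint": tp, "replicate": r + 1}
            for tp in self.timepoints
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class SimulatedAnnotation:
    """Genome + gene models + known SNPs, with the planted-site plan."""

    genome: GenomeRef
    model: TranscriptModel
    snps: SnpSet
    site_plan: pd.DataFrame          # pos, strand, gene_id, region, klass
    gene_info: pd.DataFrame          # gene_id, strand, span, cds_len, es, as_

    def __iter__(self):
        # allows: genome, model, snps = simulate_annotation(cfg)
        return iter((self.genome, self.model, self.snps))


def _tx_to_genomic(exons: list[tuple[int, int]], strand: str,
                   a: int, b: int) -> list[tuple[int, int]]:
    """Map a 1-based transcript interval [a, b] to genomic intervals."""
    out = []
    walk = exons if strand == "+" else exons[::-1]
    cursor = 1
    for s, e in walk:
        ln = e - s + 1
        lo = max(a, cursor)
        hi = min(b, cursor + ln - 1)
        if lo <= hi:
            if strand == "+":
                out.append((s + (lo - cursor), s + (hi - cursor)))
            else:
                out.append((e - (hi - cursor), e - (lo - cursor)))
        cursor += ln
    return sorted(out)


def _gene_regions(tx: Transcript) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals per placeable region class of one transcript."""
    regions: dict[str, list[tuple[int, int]]] = {
        "intron": [], "5'UTR": [], "3'UTR": [], "CDS": [], "ncRNA": [],
    }
    margin = 6  # stay clear of the 4 nt splice-proximal exclusion zone
    for (s1, e1), (s2, _) in zip(tx.exons, tx.exons[1:]):
        lo, hi = e1 + 1 + margin, s2 - 1 - margin
        if lo <= hi:
            regions["intron"].append((lo, hi))
    if not tx.cds:
        regions["ncRNA"] = list(tx.exons)
        return regions
    regions["CDS"] = list(tx.cds)
    cds_lo, cds_hi = tx.cds[0][0], tx.cds[-1][1]
    for s, e in tx.exons:
        left = (s, min(e, cds_lo - 1))
        right = (max(s, cds_hi + 1), e)
        for lo, hi in (left, right):
            if lo <= hi:
                label = "5'UTR" if (hi < cds_lo) == (tx.strand == "+") else "3'UTR"
                regions[label].append((lo, hi))
    return regions


REGION_WEIGHTS = {"intron": 0.60, "3'UTR": 0.20, "5'UTR": 0.05, "CDS": 0.15}

_CONTAMINANT_CLASSES = (
    "snp", "multiallelic", "low_support", "splice_proximal",
    "read_end", "single_rep",
)


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Toy genome, annotation and SNP set with planted site positions.

    Genes are multi-exon with introns, UTRs and a CDS divisible by 3 (10%
    are non-coding).  Editing-site positions are designated inside genes
    with an A on the transcript strand; the -1 neighbour is G-depleted and
    the +1 neighbour G-enriched by ``motif_bias``, matching the ADAR
    substrate preference.  SNP positions are the planted snp-contaminant
    positions.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])

    # ---- gene layout -------------------------------------------------
    gene_rows = []
    transcripts: dict[str, Transcript] = {}
    cursor = 1000
    chrom = "chr1"
    special = ["Adar", "Adarb1", "Adarb2"]
    for i in range(config.n_genes):
        gid = special[i] if i < len(special) else f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(3, 6))
        ex_lens = rng.integers(150, 401, n_ex)
        in_lens = rng.integers(400, 901, n_ex - 1)
        exons = []
        pos = cursor
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j]) - 1))
            pos = exons[-1][1] + 1
            if j < n_ex - 1:
                pos += int(in_lens[j])
        span = (exons[0][0], exons[-1][1])
        coding = rng.random() < 0.9 or gid in special
        cds: list[tuple[int, int]] = []
        if coding:
            T = int(ex_lens.sum())
            u5 = max(int(T * 0.15), 10)
            cds_len = max((int(T * 0.55) // 3) * 3, 30)
            cds = _tx_to_genomic(exons, strand, u5 + 1, u5 + cds_len)
        tx = Transcript(f"{gid}.t1", gid, chrom, strand, exons, cds)
        transcripts[tx.tx_id] = tx
        gene_rows.append(
            {"gene_id": gid, "chrom": chrom, "start": span[0], "end": span[1],
             "strand": strand, "cds_len": sum(e - s + 1 for s, e in cds),
             "tx_len": int(ex_lens.sum())}
        )
        cursor = span[1] + int(rng.integers(800, 2001))

    genes = pd.DataFrame(gene_rows)
    model = TranscriptModel(
        genes[["gene_id", "chrom", "start", "end", "strand"]].copy(),
        transcripts,
    )
    chrom_len = cursor + 1000

    # ---- ES / AS gene assignment ------------------------------------
    candidates = [g for g in genes["gene_id"] if g not in special]
    n_es = int(round(config.frac_es_genes * config.n_genes))
    n_as = int(round(config.frac_as_genes * config.n_genes))
    es_genes = set(rng.choice(candidates, size=min(n_es, len(candidates)),
                              replace=False))
    as_genes = set(rng.choice(candidates, size=min(n_as, len(candidates)),
                              replace=False))
    genes["es"] = genes["gene_id"].isin(es_genes)
    genes["as_"] = genes["gene_id"].isin(as_genes)

    # ---- plant site positions ---------------------------------------
    n_contam = {
        "snp": int(round(config.snp_rate * config.n_true_sites)),
        "multiallelic": int(round(config.multiallelic_rate * config.n_true_sites)),
        "low_support": int(round(config.low_support_rate * config.n_true_sites)),
        "splice_proximal": int(round(config.splice_proximal_rate * config.n_true_sites)),
        "read_end": int(round(config.read_end_rate * config.n_true_sites)),
        "single_rep": int(round(config.single_rep_rate * config.n_true_sites)),
    }
    plan_rows = []
    taken: dict[str, list[int]] = {g: [] for g in genes["gene_id"]}
    region_info = {
        t.gene_id: _gene_regions(t) for t in transcripts.values()
    }
    es_list = sorted(es_genes)
    if not es_list:
        raise ValueError(
            "genome too small: no editable genes available "
            f"(n_genes={config.n_genes}, frac_es_genes={config.frac_es_genes})"
        )
    min_gap = 110  # > 2 x read length so site reads never overlap

    def place(gene_id: str, region: str) -> int | None:
        ivals = region_info[gene_id].get(region, [])
        ivals = [iv for iv in ivals if iv[1] >= iv[0]]
        if not ivals:
            return None
        for _ in range(40):
            lo, hi = ivals[int(rng.integers(len(ivals)))]
            p = int(rng.integers(lo, hi + 1))
            if all(abs(p - q) >= min_gap for q in taken[gene_id]):
                taken[gene_id].append(p)
                return p
        return None

    def sample_region(gene_id: str) -> str:
        tx = transcripts[f"{gene_id}.t1"]
        if not tx.cds:
            return "ncRNA"
        names = list(REGION_WEIGHTS)
        probs = np.array([REGION_WEIGHTS[n] for n in names])
        return str(rng.choice(names, p=probs / probs.sum()))

    def plant(klass: str, count: int) -> None:
        placed = 0
        attempts = 0
        while placed < count and attempts < count * 30:
            attempts += 1
            gid = es_list[int(rng.integers(len(es_list)))]
            strand = genes.loc[genes["gene_id"] == gid, "strand"].iloc[0]
            if klass == "splice_proximal":
                tx = transcripts[f"{gid}.t1"]
                bounds = tx.splice_boundaries()
                if not bounds:
                    continue
                bpos, side = bounds[int(rng.integers(len(bounds)))]
                off = int(rng.integers(1, 5))
                p = bpos + off if side == "right" else bpos - off
                if not all(abs(p - q) >= min_gap for q in taken[gid]):
                    continue
                taken[gid].append(p)
                region = "intron"
            else:
                region = sample_region(gid)
                p = place(gid, region)
                if p is None:
                    continue
            plan_rows.append(
                {"pos": p, "strand": strand, "gene_id": gid,
                 "region": region, "klass": klass}
            )
            placed += 1
        if placed < count:
            raise ValueError(
                f"genome too small: placed {placed}/{count} {klass} sites "
                f"for {config.n_genes} genes"
            )

    # contaminants first: splice-proximal slots are scarce and would be
    # crowded out by the spacing constraint once true sites are placed
    for klass, count in n_contam.items():
        plant(klass, count)
    plant("true", config.n_true_sites)
    site_plan = pd.DataFrame(plan_rows)
    site_plan["chrom"] = chrom

    # ---- genome sequence with motif bias ----------------------------
    base_arr = rng.integers(0, 4, chrom_len)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[base_arr].copy()

    b = config.motif_bias
    p_bg = np.full(4, 0.25)
    p_minus1 = np.array([0.25 + b / 3, 0.25 + b / 3, 0.25 - b, 0.25 + b / 3])
    p_plus1 = np.array([0.25 - b / 3, 0.25 - b / 3, 0.25 + b, 0.25 - b / 3])
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp_code = {0: 3, 1: 2, 2: 1, 3: 0}
    for row in site_plan.itertuples(index=False):
        # transcript-strand A at the site
        site_code = code["A"] if row.strand == "+" else code["T"]
        seq[row.pos - 1] = np.frombuffer(b"ACGT", dtype=np.uint8)[site_code]
        up = int(rng.choice(4, p=p_minus1))   # -1 on transcript strand
        dn = int(rng.choice(4, p=p_plus1))    # +1 on transcript strand
        if row.strand == "+":
            gup, gdn = up, dn
            seq[row.pos - 2] = np.frombuffer(b"ACGT", dtype=np.uint8)[gup]
            seq[row.pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[gdn]
        else:
            seq[row.pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[comp_code[up]]
            seq[row.pos - 2] = np.frombuffer(b"ACGT", dtype=np.uint8)[comp_code[dn]]
    genome = GenomeRef({chrom: seq.tobytes().decode()})

    snp_positions = {
        (chrom, int(p))
        for p in site_plan.loc[site_plan["klass"] == "snp", "pos"]
    }
    snps = SnpSet(snp_positions)
    return SimulatedAnnotation(genome, model, snps, site_plan,
                               genes.set_index("gene_id"))


def _assign_trajectories(config: SimulationConfig, site_plan: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Attach a cluster label and per-time-point EL to every planted row."""
    n_tp = len(config.timepoints)
    patterns = np.asarray(config.cluster_patterns)
    truth = site_plan.copy().reset_index(drop=True)
    truth["cluster"] = -1
    els = np.zeros((len(truth), n_tp))
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.klass == "true":
            cl = int(rng.integers(len(patterns)))
            traj = np.clip(
                patterns[cl] + rng.normal(0, config.el_noise, n_tp),
                0.0, 0.98,
            )
            truth.loc[i, "cluster"] = cl + 1
        elif row.klass == "snp":
            traj = np.full(n_tp, 1.0 if rng.random() < 0.5 else 0.5)
        elif row.klass == "multiallelic":
            traj = np.full(n_tp, 0.15)
        elif row.klass == "low_support":
            flavor = ("el", "coverage", "edited")[int(rng.integers(3))]
            truth.loc[i, "low_support_flavor"] = flavor
            # el: EL < 0.02 despite deep coverage and >= 3 edited reads;
            # coverage: pooled depth < 10; edited: exactly 2 pooled edited
            traj = np.full(n_tp, {"el": 0.0, "coverage": 0.5, "edited": 0.0}[flavor])
        elif row.klass == "splice_proximal":
            traj = np.full(n_tp, 0.3)
        elif row.klass == "read_end":
            traj = np.full(n_tp, 0.3)
        elif row.klass == "single_rep":
            traj = np.full(n_tp, 0.4)
        else:
            raise ValueError(f"unknown planted class {row.klass!r}")
        els[i] = traj
    for j, tp in enumerate(config.timepoints):
        truth[f"el_{tp}"] = els[:, j]
    if "low_support_flavor" not in truth.columns:
        truth["low_support_flavor"] = np.nan
    truth["site_key"] = (
        truth["chrom"] + ":" + truth["pos"].astype(str) + ":" + truth["strand"]
    )
    return truth


def simulate_editome(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stranded read alignments realising the planted editing signal.

    Returns ``(reads, truth)``.  ``reads`` columns: read_id, chrom, start,
    strand, bases (genomic forward, as in SAM), sample.  At a true site the
    number of edited reads per replicate is Binomial(coverage, EL_t); the
    edited base is G on the transcript strand.  Contaminants realise the
    signal of their class; uniform sequencing errors at ``seq_error_rate``
    form the background of non-A-to-I mismatches.
    """
    rng = np.random.default_rng([2, config.seed])
    truth = _assign_trajectories(config, annotation.site_plan, rng)
    genome = annotation.genome
    L = config.read_length
    lo_off, hi_off = config.trim_start, L - config.trim_end - 1
    seqs = genome.sequences

    read_rows: list[tuple] = []
    rid = 0

    def emit(chrom: str, pos: int, strand: str, sample: str,
             n_ref: int, alt_counts: dict[str, int],
             offsets: str = "inner") -> None:
        """Emit reads covering ``pos``: n_ref reference + per-alt counts."""
        nonlocal rid
        seq = seqs[chrom]
        plan = [(None, n_ref)] + list(alt_counts.items())
        for alt_base, count in plan:
            if count <= 0:
                continue
            if offsets == "inner":
                offs = rng.integers(lo_off, hi_off + 1, count)
            else:  # read-end artifact offsets: outside the trimmed window
                pool = np.concatenate(
                    [np.arange(0, config.trim_start),
                     np.arange(L - config.trim_end, L)]
                )
                offs = rng.choice(pool, size=count)
            for o in offs:
                o = int(o)
                if strand == "+":
                    start = pos - o
                else:
                    end = pos + o
                    start = end - L + 1
                if start < 1 or start + L - 1 > len(seq):
                    continue
                bases = seq[start - 1: start + L - 1]
                if alt_base is not None:
                    col = pos - start
                    gbase = alt_base if strand == "+" else COMPLEMENT[alt_base]
                    bases = bases[:col] + gbase + bases[col + 1:]
                read_rows.append(
                    (f"r{rid}", chrom, start, strand, bases, sample)
                )
                rid += 1

    tp_of = {s: s.rsplit("_r", 1)[0] for s in config.samples}
    rep_of = {s: int(s.rsplit("_r", 1)[1]) for s in config.samples}

    for row in truth.itertuples(index=False):
        for sample in config.samples:
            tp = tp_of[sample]
            el = getattr(row, f"el_{tp}")
            cov_mean = config.coverage_mean
            flavor = row.low_support_flavor
            if row.klass == "low_support" and flavor == "coverage":
                # pooled depth must stay below 10: 1-4 reads per replicate
                n = int(rng.integers(1, 5))
            elif row.klass == "low_support" and flavor == "el":
                n = int(rng.poisson(200.0))
            else:
                n = int(rng.poisson(cov_mean))
            if n == 0:
                continue
            if row.klass == "multiallelic":
                k = rng.multinomial(n, [0.15, 0.10, 0.75])
                emit(row.chrom, row.pos, row.strand, sample,
                     int(k[2]), {"G": int(k[0]), "T": int(k[1])})
            elif row.klass == "read_end":
                k = int(rng.binomial(n, el))
                emit(row.chrom, row.pos, row.strand, sample, n - k, {})
                emit(row.chrom, row.pos, row.strand, sample, 0, {"G": k},
                     offsets="edge")
            elif row.klass == "single_rep":
                k = int(rng.binomial(n, el)) if rep_of[sample] == 1 else 0
                emit(row.chrom, row.pos, row.strand, sample, n - k, {"G": k})
            elif row.klass == "low_support" and flavor == "edited":
                # exactly one edited read per replicate: pooled 2 < 3
                emit(row.chrom, row.pos, row.strand, sample, n - 1, {"G": 1})
            elif row.klass == "low_support" and flavor == "el":
                # exactly 3 edited of ~200 per replicate: EL ~0.015 < 0.02
                emit(row.chrom, row.pos, row.strand, sample, n - 3, {"G": 3})
            else:
                k = int(rng.binomial(n, el))
                emit(row.chrom, row.pos, row.strand, sample, n - k, {"G": k})

    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "chrom", "start", "strand", "bases", "sample"],
    )

    # uniform sequencing-error background; planted contaminant positions are
    # excluded so each contaminant class stays removable by exactly its
    # intended filter (an error read there would corrupt the class)
    if config.seq_error_rate > 0 and len(reads):
        contam = truth.loc[truth["klass"] != "true"]
        protected = set(zip(contam["chrom"], contam["pos"]))
        n_bases = len(reads) * L
        n_err = int(rng.binomial(n_bases, config.seq_error_rate))
        if n_err:
            ridx = rng.integers(0, len(reads), n_err)
            roff = rng.integers(0, L, n_err)
            starts = reads["start"].to_numpy()
            chroms = reads["chrom"].to_numpy()
            bases_col = reads["bases"].to_numpy().copy()
            for i, o in zip(ridx, roff):
                if (chroms[i], int(starts[i]) + int(o)) in protected:
                    continue
                s = bases_col[i]
                old = s[o]
                choices = [b for b in "ACGT" if b != old]
                bases_col[i] = s[:o] + choices[int(rng.integers(3))] + s[o + 1:]
            reads["bases"] = bases_col
    return reads, truth


def _correlated_traj(z_el: np.ndarray, rho: float,
                     rng: np.random.Generator) -> np.ndarray:
    """A z-scored trajectory with sample correlation exactly rho to z_el."""
    n = len(z_el)
    eta = rng.normal(size=n)
    eta = eta - eta.mean()
    # orthogonalise against z_el, then normalise both to unit norm
    proj = (eta @ z_el) / (z_el @ z_el)
    eta = eta - proj * z_el
    if np.linalg.norm(eta) < 1e-12:
        eta = np.roll(z_el, 1) - np.roll(z_el, 1).mean()
        eta = eta - ((eta @ z_el) / (z_el @ z_el)) * z_el
    eta = eta / np.linalg.norm(eta)
    base = z_el / np.linalg.norm(z_el)
    v = rho * base + np.sqrt(max(0.0, 1 - rho ** 2)) * eta
    v = v / np.sqrt((v ** 2).mean())  # back to z-score scale (sd 1)
    return v


EVENT_TYPE_PROBS = {"IR": 0.4, "EX": 0.3, "Alt3": 0.1, "Alt5": 0.1, "MIC": 0.1}
EVENT_SEGMENT_LEN = {"IR": 300, "EX": 150, "Alt3": 30, "Alt5": 30, "MIC": 12}


def simulate_splicing(
    config: SimulationConfig,
    truth: pd.DataFrame,
    annotation: SimulatedAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Junction-count tables with PSI trajectories tied to nearby editing.

    ``n_paired_sites`` true sites in genes carrying both editing and
    splicing get a same-gene event whose z-scored PSI trajectory has
    correlation +/- ``editing_splicing_rho`` with the site's EL trajectory.
    Positively correlated events are placed 0-200 nt from their site,
    negatively correlated ones 600-1500 nt away.  Additional unpaired
    events (all five types) fill the remaining AS genes.

    Returns (events, inclusion, exclusion, ir_balance, event_truth).
    """
    if abs(config.editing_splicing_rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng([3, config.seed])
    gene_info = annotation.gene_info
    as_genes = set(gene_info.index[gene_info["as_"]])
    n_tp = len(config.timepoints)
    el_cols = [f"el_{tp}" for tp in config.timepoints]

    true_sites = truth.loc[truth["klass"] == "true"]
    pairable = true_sites.loc[true_sites["gene_id"].isin(as_genes)]
    n_pairs = min(config.n_paired_sites, len(pairable))
    chosen = pairable.sample(n=n_pairs, random_state=int(rng.integers(2 ** 31)))

    event_rows = []
    psi_traj = {}
    event_truth_rows = []
    eid = 0
    paired_genes: set[str] = set()

    for i, (_, site) in enumerate(chosen.iterrows()):
        sign = 1.0 if i % 2 == 0 else -1.0
        gid = site["gene_id"]
        paired_genes.add(gid)
        g = gene_info.loc[gid]
        etype = str(rng.choice(list(EVENT_TYPE_PROBS),
                               p=list(EVENT_TYPE_PROBS.values())))
        seg_len = EVENT_SEGMENT_LEN[etype]
        if sign > 0:
            d = int(rng.integers(0, 201))
        else:
            d = int(rng.integers(600, 1501))
        pos = int(site["pos"])
        room_right = int(g["end"]) - pos
        room_left = pos - int(g["start"])
        if room_right >= d + seg_len:
            start = pos + d
        elif room_left >= d + seg_len:
            start = pos - d - seg_len
        else:  # clamp: place as far as the gene allows on the wider side
            if room_right >= room_left:
                start = max(pos, int(g["end"]) - seg_len)
            else:
                start = int(g["start"])
        end = start + seg_len - 1

        el = site[el_cols].to_numpy(dtype=float)
        z_el = el - el.mean()
        if np.linalg.norm(z_el) < 1e-9:
            z_el = rng.normal(size=n_tp)
            z_el -= z_el.mean()
        z_psi = _correlated_traj(z_el, sign * config.editing_splicing_rho, rng)
        psi = np.clip(50.0 + 18.0 * z_psi, 2.0, 98.0)

        event_id = f"EV{eid:05d}"
        eid += 1
        event_rows.append(
            {"event_id": event_id, "gene_id": gid, "type": etype,
             "chrom": site["chrom"], "start": start, "end": end}
        )
        psi_traj[event_id] = psi
        event_truth_rows.append(
            {"event_id": event_id, "gene_id": gid, "type": etype,
             "paired_site": site["site_key"], "pair_sign":
                 "pos" if sign > 0 else "neg", "distance_planted": d,
             **{f"psi_{tp}": psi[j] for j, tp in enumerate(config.timepoints)}}
        )

    # unpaired events in AS genes without planted pairs
    free_genes = np.array(sorted(as_genes - paired_genes), dtype=object)
    rng.shuffle(free_genes)
    types_cycle = list(EVENT_TYPE_PROBS)
    for j in range(min(config.n_unpaired_events, len(free_genes))):
        gid = free_genes[j]
        g = gene_info.loc[gid]
        etype = types_cycle[j % len(types_cycle)]
        seg_len = EVENT_SEGMENT_LEN[etype]
        start = int(rng.integers(int(g["start"]), max(int(g["end"]) - seg_len,
                                                      int(g["start"]) + 1)))
        end = start + seg_len - 1
        base = float(rng.uniform(20, 80))
        wobble = rng.normal(0, 6, n_tp)
        psi = np.clip(base + wobble, 2.0, 98.0)
        event_id = f"EV{eid:05d}"
        eid += 1
        event_rows.append(
            {"event_id": event_id, "gene_id": gid, "type": etype,
             "chrom": "chr1", "start": start, "end": end}
        )
        psi_traj[event_id] = psi
        event_truth_rows.append(
            {"event_id": event_id, "gene_id": gid, "type": etype,
             "paired_site": "", "pair_sign": "", "distance_planted": np.nan,
             **{f"psi_{tp}": psi[k] for k, tp in enumerate(config.timepoints)}}
        )

    events = pd.DataFrame(event_rows).set_index("event_id")
    samples = config.samples
    inc = pd.DataFrame(0, index=events.index, columns=samples, dtype=int)
    exc = pd.DataFrame(0, index=events.index, columns=samples, dtype=int)
    tp_index = {tp: j for j, tp in enumerate(config.timepoints)}
    for event_id, psi in psi_traj.items():
        for s in samples:
            tp = s.rsplit("_r", 1)[0]
            n = int(rng.poisson(config.junction_coverage))
            k = int(rng.binomial(n, psi[tp_index[tp]] / 100.0)) if n else 0
            inc.loc[event_id, s] = k
            exc.loc[event_id, s] = n - k
    ir_rows = {}
    for event_id in events.index[events["type"] == "IR"]:
        n = int(rng.poisson(config.junction_coverage))
        a = int(rng.binomial(n, 0.5)) if n else 0
        ir_rows[event_id] = (a, n - a)
    ir_balance = pd.DataFrame.from_dict(
        ir_rows, orient="index", columns=["boundary1", "boundary2"]
    )
    event_truth = pd.DataFrame(event_truth_rows).set_index("event_id")
    return events.reset_index(), inc, exc, ir_balance, event_truth


def simulate_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    annotation: SimulatedAnnotation,
    event_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """RNA and Ribo count matrices with planted TE fold changes.

    Counts are NB(mean = expression x CDS-length(kb) x size factor x TE
    multiplier for Ribo; variance = mu + alpha mu^2).  ``n_dte_genes``
    genes change TE by 2^(+/- te_log2fc) at a random adjacent time-point
    boundary.  The Adarb1 (ADAR2) gene's expression follows the planted
    per-time-point count of active editing sites, so editing activity and
    ADAR2 expression are positively coupled as in the real system.

    Returns (rna_counts, ribo_counts, size_factor_truth, te_truth).
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng([4, config.seed])
    gene_info = annotation.gene_info
    genes = list(gene_info.index)
    n_tp = len(config.timepoints)
    tps = list(config.timepoints)

    # effective CDS length in kb (transcript length for non-coding genes)
    len_kb = gene_info["cds_len"].where(gene_info["cds_len"] > 0,
                                        gene_info["tx_len"]) / 1000.0

    expr = pd.Series(
        rng.lognormal(np.log(config.count_mean), 0.6, len(genes)), index=genes
    )
    # ADAR2 follows editing activity; a mild rise for Adar, flat Adarb2
    el_cols = [f"el_{tp}" for tp in tps]
    active = (
        truth.loc[truth["klass"] == "true", el_cols].ge(0.05).sum(axis=0)
        .to_numpy(dtype=float)
    )
    active = active / active.mean()
    expr_traj = pd.DataFrame(1.0, index=genes, columns=tps)
    expr_traj.loc["Adarb1"] = active
    expr_traj.loc["Adar"] = np.linspace(0.8, 1.2, n_tp)

    te_base = pd.Series(rng.lognormal(0.0, 0.2, len(genes)), index=genes)
    te_mult = pd.DataFrame(1.0, index=genes, columns=tps)
    dte_rows = []
    # bias planted dTE direction downward more strongly for genes that also
    # carry splicing and editing, echoing the buffering effect
    pool = [g for g in genes if g not in ("Adar", "Adarb1", "Adarb2")]
    dte_genes = rng.choice(pool, size=min(config.n_dte_genes, len(pool)),
                           replace=False)
    p_down = {(True, True): 0.88, (True, False): 0.68,
              (False, True): 0.66, (False, False): 0.5}
    for g in dte_genes:
        key = (bool(gene_info.loc[g, "as_"]), bool(gene_info.loc[g, "es"]))
        down = rng.random() < p_down[key]
        boundary = int(rng.integers(0, n_tp - 1))
        sign = -1.0 if down else 1.0
        mult = 2.0 ** (sign * config.te_log2fc)
        te_mult.loc[g, tps[boundary + 1:]] = mult
        dte_rows.append(
            {"gene_id": g, "boundary": f"{tps[boundary + 1]}_vs_{tps[boundary]}",
             "log2fc": sign * config.te_log2fc,
             "direction": "down" if down else "up"}
        )
    te_truth = pd.DataFrame(dte_rows)

    samples_rna = [f"{tp}_r{r + 1}" for tp in tps for r in range(config.n_replicates)]
    sf = {}
    counts = {"RNA": {}, "Ribo": {}}
    alpha = config.nb_dispersion
    for lib in ("RNA", "Ribo"):
        for s in samples_rna:
            tp = s.rsplit("_r", 1)[0]
            f = float(rng.uniform(0.75, 1.3))
            sf[(lib, s)] = f
            mu = (
                expr.to_numpy()
                * expr_traj[tp].to_numpy()
                * len_kb.to_numpy()
                * f
            )
            if lib == "Ribo":
                mu = mu * te_base.to_numpy() * te_mult[tp].to_numpy()
            n_param = 1.0 / alpha
            p = n_param / (n_param + mu)
            counts[lib][s] = rng.negative_binomial(n_param, p)
    rna = pd.DataFrame(counts["RNA"], index=genes)
    ribo = pd.DataFrame(counts["Ribo"], index=genes)
    sf_truth = pd.DataFrame(
        [{"libtype": k[0], "sample": k[1], "size_factor": v} for k, v in sf.items()]
    )
    return rna, ribo, sf_truth, te_truth


def translatable_counts(
    config: SimulationConfig, annotation: SimulatedAnnotation,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-gene translatable-transcript counts ordered by AS/ES class."""
    rng = rng or np.random.default_rng([5, config.seed])
    gene_info = annotation.gene_info
    means = {(True, True): 4.0, (True, False): 3.0,
             (False, True): 2.0, (False, False): 1.0}
    vals = [
        1 + rng.poisson(means[(bool(r["as_"]), bool(r["es"]))])
        for _, r in gene_info.iterrows()
    ]
    return pd.Series(vals, index=gene_info.index, name="translatable")


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the truth tables."""

    config: SimulationConfig
    annotation: SimulatedAnnotation
    reads: pd.DataFrame
    truth: pd.DataFrame
    events: pd.DataFrame
    inclusion: pd.DataFrame
    exclusion: pd.DataFrame
    ir_balance: pd.DataFrame
    event_truth: pd.DataFrame
    rna_counts: pd.DataFrame
    ribo_counts: pd.DataFrame
    size_factor_truth: pd.DataFrame
    te_truth: pd.DataFrame
    translatable: pd.Series

    def sample_sheet(self) -> pd.DataFrame:
        return self.config.sample_sheet()

    def pileup(self) -> pd.DataFrame:
        return calling.build_pileup(
            self.reads, self.annotation.genome,
            trim_start=self.config.trim_start, trim_end=self.config.trim_end,
        )


def simulate_all(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run every simulator stage with seeds derived from the root seed."""
    config = config or SimulationConfig()
    config.validate()
    annotation = simulate_annotation(config)
    reads, truth = simulate_editome(config, annotation)
    events, inc, exc, ir_bal, event_truth = simulate_splicing(
        config, truth, annotation
    )
    rna, ribo, sf_truth, te_truth = simulate_expression(
        config, truth, annotation, event_truth
    )
    trans = translatable_counts(config, annotation)
    return SimulatedDataset(
        config=config, annotation=annotation, reads=reads, truth=truth,
        events=events, inclusion=inc, exclusion=exc, ir_balance=ir_bal,
        event_truth=event_truth, rna_counts=rna, ribo_counts=ribo,
        size_factor_truth=sf_truth, te_truth=te_truth, translatable=trans,
    )
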