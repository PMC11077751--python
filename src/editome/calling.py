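"""High-confidence editing-site calling from stranded read alignments.

The calling path mirrors a mismatch-pileup editing pipeline: reads are
trimmed at both ends (the start of a read carries random-priming and
recalibration artifacts), base counts are accumulated per sample on the
transcript strand, every position with at least one alternative base becomes
a candidate, and a five-step filter cascade retains high-confidence sites:

1. presence in both replicates of a time point,
2. read-end trimming (12 nt from the start, 2 nt from the end),
3. exclusion of known SNP positions and of positions within 4 nt on the
   intronic side of annotated splice sites,
4. removal of multiallelic positions (more than one variant base),
5. support thresholds: editing level >= 0.02, coverage >= 10 reads and
   >= 3 edited reads.

Editing level (EL) is edited / covered.  On minus-strand genes a genomic
T->C mismatch is reported on the transcript strand as type "AG", the A-to-I
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import COMPLEMENT, GenomeRef, SnpSet, TranscriptModel, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {ord(b): i for i, b in enumerate(_BASES)}
# uint8 ASCII -> base index; 255 marks non-ACGT (N etc.)
_LUT = np.full(256, 255, dtype=np.uint8)
for _code, _idx in _BASE_INDEX.items():
    _LUT[_code] = _idx
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


@dataclass
class FilterThresholds:
    """Support thresholds of the high-confidence cascade."""

    min_el: float = 0.02
    min_coverage: int = 10
    min_edited: int = 3
    splice_intronic_nt: int = 4
    strict_replicates: bool = False  # support thresholds per replicate too

    def validate(self) -> None:
        if not 0 <= self.min_el <= 1:
            raise ValueError("min_el must be in [0, 1]")
        if self.min_coverage < 0 or self.min_edited < 0 or self.splice_intronic_nt < 0:
            raise ValueError("count thresholds must be non-negative")


def build_pileup(reads: pd.DataFrame, genome: GenomeRef,
                 trim_start: int = 12, trim_end: int = 2) -> pd.DataFrame:
    """Accumulate transcript-strand base counts from gapless read alignments.

    ``reads`` columns: read_id, chrom, start (1-based leftmost), strand
    ("+" or "-", the transcript strand of the fragment), bases (genomic
    forward orientation, as in SAM), sample.

    Only read offsets ``[trim_start, len - trim_end)`` counted along the
    *biological* read direction contribute; for a minus-strand read the
    biological start is its genomic right end.  Reads shorter than
    ``trim_start + trim_end`` contribute nothing (logged).

    Returns a tidy pileup: chrom, pos, strand, sample, ref (transcript
    strand) and A/C/G/T counts (transcript strand).
    """
    if trim_start < 0 or trim_end < 0:
        raise ValueError("trim lengths must be non-negative")
    if reads.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "sample", "ref", "A", "C", "G", "T"]
        )

    chrom_codes, chrom_names = pd.factorize(reads["chrom"])
    sample_codes, sample_names = pd.factorize(reads["sample"])
    strand_codes = (reads["strand"].to_numpy() == "-").astype(np.int64)

    n_samples = len(sample_names)
    max_pos = max(len(s) for s in genome.sequences.values()) + 2

    key_parts = []
    lengths = reads["bases"].str.len()
    n_skipped = 0
    for L, idx in lengths.groupby(lengths).groups.items():
        L = int(L)
        if L <= trim_start + trim_end:
            n_skipped += len(idx)
            continue
        sub = reads.loc[idx]
        loc = reads.index.get_indexer(idx)
        mat = np.frombuffer("".join(sub["bases"]).encode(), dtype=np.uint8)
        mat = _LUT[mat].reshape(len(sub), L)
        starts = sub["start"].to_numpy(dtype=np.int64)
        minus = strand_codes[loc] == 1
        # trimmed window in genomic-forward column coordinates: for a minus
        # read the biological start sits at the genomic right end
        for is_minus, (a, b) in ((False, (trim_start, L - trim_end)),
                                 (True, (trim_end, L - trim_start))):
            rows = minus if is_minus else ~minus
            if not rows.any():
                continue
            W = b - a
            bb = mat[rows, a:b].ravel().astype(np.int64)
            if is_minus:
                ok = bb != 255
                bb[ok] = _COMP_IDX[bb[ok]]
            valid = bb != 255
            # key = (((chrom * max_pos + pos) * 2 + strand) * n_samples
            #        + sample) * 4 + base, built in place
            key = np.repeat(chrom_codes[loc][rows].astype(np.int64), W)
            key *= max_pos
            key += (starts[rows, None]
                    + np.arange(a, b, dtype=np.int64)[None, :]).ravel()
            key *= 2
            if is_minus:
                key += 1
            key *= n_samples
            key += np.repeat(sample_codes[loc][rows].astype(np.int64), W)
            key *= 4
            key += bb
            key_parts.append(key[valid])
    if n_skipped:
        logger.info("build_pileup: %d reads shorter than trim window skipped", n_skipped)
    if not key_parts:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "sample", "ref", "A", "C", "G", "T"]
        )

    key = np.concatenate(key_parts)
    del key_parts
    uniq, counts = np.unique(key, return_counts=True)

    b = uniq % 4
    rest = uniq // 4
    s = rest % n_samples
    rest //= n_samples
    strand = rest % 2
    rest //= 2
    p = rest % max_pos
    c = rest // max_pos

    row_key = ((c * max_pos + p) * 2 + strand) * n_samples + s
    row_uniq, row_idx = np.unique(row_key, return_inverse=True)
    count_mat = np.zeros((len(row_uniq), 4), dtype=np.int64)
    count_mat[row_idx, b] = counts

    rs = row_uniq % n_samples
    rest = row_uniq // n_samples
    rstrand = rest % 2
    rest //= 2
    rp = rest % max_pos
    rc = rest // max_pos

    out = pd.DataFrame(
        {
            "chrom": chrom_names.take(rc),
            "pos": rp,
            "strand": np.where(rstrand == 1, "-", "+"),
            "sample": sample_names.take(rs),
            "A": count_mat[:, 0],
            "C": count_mat[:, 1],
            "G": count_mat[:, 2],
            "T": count_mat[:, 3],
        }
    )
    refs = np.empty(len(out), dtype="U1")
    for chrom, grp in out.groupby("chrom", sort=False):
        seq = genome.sequences[chrom]
        neg = grp["strand"].to_numpy() == "-"
        vals = [
            COMPLEMENT[seq[p - 1]] if m else seq[p - 1]
            for p, m in zip(grp["pos"].to_numpy(), neg)
        ]
        refs[out.index.get_indexer(grp.index)] = vals
    out["ref"] = refs
    out = out[["chrom", "pos", "strand", "sample", "ref", "A", "C", "G", "T"]]
    return out.sort_values(["chrom", "pos", "sample"], ignore_index=True)


def call_candidates(pileup: pd.DataFrame, genome: GenomeRef,
                    annotation: TranscriptModel | None = None) -> pd.DataFrame:
    """One candidate per (position, alt base) with at least one alt read.

    The pileup is already on the transcript strand, so the editing type is
    simply ref+alt there ("AG" marks A-to-I).  When an annotation is given,
    the annotated gene strand overrides the read-derived strand tag (counts
    are re-complemented if they disagree).  Positions with an N reference
    are skipped and logged.

    Returns one row per (site, sample): chrom, pos, strand, ref, alt, etype,
    sample, covered, edited, el.
    """
    if pileup.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "ref", "alt", "etype",
                     "sample", "covered", "edited", "el"]
        )
    pu = pileup.copy()
    if annotation is not None:
        key = pu[["chrom", "pos"]].drop_duplicates()
        strands = {
            (c, p): annotation.strand_at(c, p) for c, p in key.itertuples(index=False)
        }
        ann = pu.set_index(["chrom", "pos"]).index.map(strands.get)
        ann = pd.Series(ann, index=pu.index)
        flip = ann.notna() & (ann != pu["strand"])
        if flip.any():
            sub = pu.loc[flip]
            pu.loc[flip, ["A", "C", "G", "T"]] = sub[["T", "G", "C", "A"]].to_numpy()
            pu.loc[flip, "ref"] = sub["ref"].map(COMPLEMENT).to_numpy()
            pu.loc[flip, "strand"] = ann[flip]

    n_ref = pu["ref"] == "N"
    if n_ref.any():
        logger.info("call_candidates: %d pileup rows with N reference skipped",
                    int(n_ref.sum()))
        pu = pu.loc[~n_ref]

    counts = pu[list(_BASES)].to_numpy()
    covered = counts.sum(axis=1)
    rows = []
    ref_idx = np.array([_BASES.index(b) for b in pu["ref"]])
    for ai, alt in enumerate(_BASES):
        has_alt = (counts[:, ai] >= 1) & (ref_idx != ai)
        if not has_alt.any():
            continue
        sub = pu.loc[has_alt, ["chrom", "pos", "strand", "ref", "sample"]].copy()
        sub["alt"] = alt
        sub["covered"] = covered[has_alt]
        sub["edited"] = counts[has_alt, ai]
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "ref", "alt", "etype",
                     "sample", "covered", "edited", "el"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["etype"] = out["ref"] + out["alt"]
    out["el"] = out["edited"] / out["covered"]
    out = out[["chrom", "pos", "strand", "ref", "alt", "etype",
               "sample", "covered", "edited", "el"]]
    return out.sort_values(["chrom", "pos", "alt", "sample"], ignore_index=True)


def _coverage_table(pileup: pd.DataFrame) -> pd.DataFrame:
    """Per (chrom,pos,sample) total coverage, used to fill unedited samples."""
    cov = pileup.copy()
    cov["covered"] = cov[list(_BASES)].sum(axis=1)
    return cov[["chrom", "pos", "sample", "covered"]]


def filter_cascade(
    candidates: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    snps: SnpSet,
    annotation: TranscriptModel,
    thresholds: FilterThresholds | None = None,
    pileup: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the high-confidence filter cascade per time point.

    ``sample_sheet`` columns: sample, timepoint, replicate.  Candidates are
    evaluated within each time point: a (position, type) must be detected in
    both replicates; SNP positions, splice-proximal positions (within
    ``splice_intronic_nt`` nt on the intronic side of a boundary) and
    multiallelic positions are removed; finally pooled counts must satisfy
    EL >= min_el, coverage >= min_coverage and edited >= min_edited.  With
    ``strict_replicates`` the support thresholds apply per replicate instead
    of to pooled counts.

    Returns ``(sites, presence, attrition)``:

    - sites: one row per surviving (site, timepoint) with pooled counts,
      keyed by site_id "chrom:pos:strand:alt";
    - presence: site_id x timepoint boolean survival matrix;
    - attrition: counts per (timepoint, stage) remaining after each stage.
    """
    th = thresholds or FilterThresholds()
    th.validate()

    cand = candidates.merge(sample_sheet, on="sample", how="left")
    if cand["timepoint"].isna().any():
        missing = cand.loc[cand["timepoint"].isna(), "sample"].unique()
        raise ValueError(f"samples missing from sample sheet: {missing}")

    n_reps = sample_sheet.groupby("timepoint")["replicate"].nunique()
    proximal = annotation.splice_proximal_positions(th.splice_intronic_nt)

    stage_rows = []
    survivors = []
    for tp, sub in cand.groupby("timepoint", sort=False):
        nalt = sub.groupby(["chrom", "pos"])["alt"].nunique()
        multi_positions = set(nalt[nalt > 1].index)

        def log_stage(name: str, frame: pd.DataFrame) -> None:
            n = frame[["chrom", "pos", "alt"]].drop_duplicates().shape[0]
            stage_rows.append({"timepoint": tp, "stage": name, "n_sites": n})

        log_stage("candidates", sub)

        # (1) both replicates of this time point
        det = sub.groupby(["chrom", "pos", "strand", "ref", "alt"])["replicate"].nunique()
        concordant = det[det >= n_reps[tp]].index
        sub = sub.set_index(["chrom", "pos", "strand", "ref", "alt"])
        sub = sub.loc[sub.index.isin(concordant)].reset_index()
        log_stage("both_replicates", sub)

        # (3a) SNP positions
        in_snp = [(c, p) in snps for c, p in zip(sub["chrom"], sub["pos"])]
        sub = sub.loc[~np.array(in_snp, dtype=bool)] if len(sub) else sub
        log_stage("snp", sub)

        # (3b) splice-proximal intronic positions
        if len(sub):
            near = [(c, p) in proximal for c, p in zip(sub["chrom"], sub["pos"])]
            sub = sub.loc[~np.array(near, dtype=bool)]
        log_stage("splice_proximal", sub)

        # (4) multiallelic positions: >1 variant base at the position in any
        # sample of this time point (raw candidate evidence, not only
        # replicate-concordant alleles)
        if len(sub):
            keep = [
                (c, p) not in multi_positions
                for c, p in zip(sub["chrom"], sub["pos"])
            ]
            sub = sub.loc[np.array(keep, dtype=bool)]
        log_stage("multiallelic", sub)

        # (5) support thresholds on pooled (or per-replicate) counts
        if len(sub):
            pooled = sub.groupby(
                ["chrom", "pos", "strand", "ref", "alt", "etype"], as_index=False
            ).agg(covered=("covered", "sum"), edited=("edited", "sum"))
            pooled["el"] = pooled["edited"] / pooled["covered"]
            ok = (
                (pooled["el"] >= th.min_el)
                & (pooled["covered"] >= th.min_coverage)
                & (pooled["edited"] >= th.min_edited)
            )
            pooled = pooled.loc[ok]
            if th.strict_replicates:
                per_rep = sub.copy()
                rep_ok = (
                    (per_rep["el"] >= th.min_el)
                    & (per_rep["covered"] >= th.min_coverage)
                    & (per_rep["edited"] >= th.min_edited)
                )
                n_ok = per_rep.loc[rep_ok].groupby(
                    ["chrom", "pos", "strand", "ref", "alt"]
                )["replicate"].nunique()
                strict_idx = set(n_ok[n_ok >= n_reps[tp]].index)
                keep = [
                    (c, p, s, r, a) in strict_idx
                    for c, p, s, r, a in pooled[
                        ["chrom", "pos", "strand", "ref", "alt"]
                    ].itertuples(index=False)
                ]
                pooled = pooled.loc[np.array(keep, dtype=bool)]
            pooled["timepoint"] = tp
        else:
            pooled = pd.DataFrame(
                columns=["chrom", "pos", "strand", "ref", "alt", "etype",
                         "covered", "edited", "el", "timepoint"]
            )
        log_stage("support", pooled)
        survivors.append(pooled)

    sites = pd.concat(survivors, ignore_index=True)
    if len(sites):
        sites["site_id"] = (
            sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
            + ":" + sites["strand"] + ":" + sites["alt"]
        )
    else:
        sites["site_id"] = pd.Series(dtype=str)
    tps = list(sample_sheet["timepoint"].drop_duplicates())
    presence = (
        sites.assign(present=True)
        .pivot_table(index="site_id", columns="timepoint", values="present",
                     aggfunc="any", fill_value=False)
        .reindex(columns=tps, fill_value=False)
        if len(sites)
        else pd.DataFrame(columns=tps)
    )
    attrition = pd.DataFrame(stage_rows)
    # invariant: the cascade is monotone and the final set satisfies thresholds
    _assert_cascade(sites, attrition, th)
    return sites, presence, attrition


def _assert_cascade(sites: pd.DataFrame, attrition: pd.DataFrame,
                    th: FilterThresholds) -> None:
    for tp, grp in attrition.groupby("timepoint"):
        ns = grp["n_sites"].tolist()
        if any(b > a for a, b in zip(ns, ns[1:])):
            raise AssertionError(f"filter cascade not monotone at {tp}: {ns}")
    if len(sites):
        assert (sites["el"] >= th.min_el).all()
        assert (sites["covered"] >= th.min_coverage).all()
        assert (sites["edited"] >= th.min_edited).all()


def annotate_sites(sites: pd.DataFrame, annotation: TranscriptModel,
                   genome: GenomeRef) -> pd.DataFrame:
    """Assign a region class per site; drop ambiguous annotations.

    Region classes: CDS-synonymous, CDS-nonsynonymous, 5'UTR, 3'UTR, intron,
    ncRNA, intergenic.  CDS calls recompute the codon with the alternative
    base substituted on the coding strand.
    """
    if sites.empty:
        out = sites.copy()
        out["region"] = pd.Series(dtype=str)
        out["gene_id"] = pd.Series(dtype=str)
        return out
    uniq = sites[["site_id", "chrom", "pos", "strand", "alt"]].drop_duplicates("site_id")
    regions = {}
    genes = {}
    for sid, chrom, pos, strand, alt in uniq.itertuples(index=False):
        region, ambiguous = annotation.region_annotation(chrom, pos)
        hits = annotation.genes_at(chrom, pos)
        genes[sid] = hits[0][0] if hits else ""
        if ambiguous:
            regions[sid] = "ambiguous"
            continue
        if region == "CDS":
            region = _classify_cds(chrom, pos, alt, strand, annotation, genome)
        regions[sid] = region
    out = sites.copy()
    out["region"] = out["site_id"].map(regions)
    out["gene_id"] = out["site_id"].map(genes)
    n_amb = (out["region"] == "ambiguous").sum()
    if n_amb:
        logger.info("annotate_sites: %d site rows dropped as ambiguous", n_amb)
    return out.loc[out["region"] != "ambiguous"].reset_index(drop=True)


def _classify_cds(chrom: str, pos: int, alt: str, strand: str,
                  annotation: TranscriptModel, genome: GenomeRef) -> str:
    """Synonymous/nonsynonymous status of a CDS substitution."""
    from .io_formats import CODON_TABLE

    for gid, gstrand in annotation.genes_at(chrom, pos):
        for tx in annotation.gene_transcripts(gid):
            if not tx.cds or not any(s <= pos <= e for s, e in tx.cds):
                continue
            if tx.cds_length % 3 != 0:
                raise ValueError(
                    f"transcript {tx.tx_id}: CDS length {tx.cds_length} "
                    "not divisible by 3"
                )
            coding = "".join(genome.fetch(chrom, s, e) for s, e in tx.cds)
            offset = 0
            idx = None
            for s, e in tx.cds:
                if s <= pos <= e:
                    idx = offset + (pos - s)
                    break
                offset += e - s + 1
            if tx.strand == "-":
                coding = revcomp(coding)
                idx = len(coding) - 1 - idx
            codon_i = idx // 3
            codon = list(coding[codon_i * 3: codon_i * 3 + 3])
            # alt is on the transcript strand, which is the coding strand
            alt_coding = alt if tx.strand == strand else COMPLEMENT[alt]
            before = CODON_TABLE["".join(codon)]
            codon[idx % 3] = alt_coding
            after = CODON_TABLE["".join(codon)]
            return "CDS-synonymous" if before == after else "CDS-nonsynonymous"
    return "CDS-nonsynonymous"


def context_matrix(sites: pd.DataFrame, genome: GenomeRef, k: int = 1) -> pd.DataFrame:
    """Base frequencies at offsets -k..+k around sites, on the editing strand.

    Offset 0 is the edited base itself.  Offsets falling outside a
    chromosome are skipped, with each offset normalised by its own count.
    """
    uniq = sites[["chrom", "pos", "strand"]].drop_duplicates()
    offsets = list(range(-k, k + 1))
    counts = pd.DataFrame(0, index=offsets, columns=list(_BASES), dtype=float)
    for chrom, pos, strand in uniq.itertuples(index=False):
        seq = genome.sequences[chrom]
        for off in offsets:
            goff = off if strand == "+" else -off
            p = pos + goff
            if not 1 <= p <= len(seq):
                continue
            b = seq[p - 1]
            if strand == "-":
                b = COMPLEMENT[b]
            if b in _BASES:
                counts.loc[off, b] += 1
    totals = counts.sum(axis=1)
    freq = counts.div(totals.replace(0, np.nan), axis=0)
    freq.index.name = "offset"
    return freq


def editing_level_by_timepoint(
    candidates: pd.DataFrame, sample_sheet: pd.DataFrame,
    pileup: pd.DataFrame | None = None,
    method: str = "pooled", min_coverage_defined: int = 1,
) -> pd.DataFrame:
    """Per-site, per-time-point editing level.

    ``method`` "pooled" (default) sums edited and covered reads over the
    replicates of a time point before taking the ratio, weighting replicates
    by their coverage; "mean" averages per-replicate ratios.

    When ``pileup`` is given, position coverage comes from the pileup for
    every sample, so a covered-but-unedited time point yields EL 0 (absence
    of editing is a measurement).  Without it, coverage is known only where
    the alternative base was detected.  Time points whose pooled coverage is
    below ``min_coverage_defined`` are left missing rather than set to zero.

    Returns a site_id x timepoint matrix of ELs.
    """
    df = candidates.merge(sample_sheet, on="sample", how="left").copy()
    df["site_id"] = (
        df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        + ":" + df["strand"] + ":" + df["alt"]
    )
    tps = list(sample_sheet["timepoint"].drop_duplicates())
    if method == "mean":
        sub = df[df["covered"] >= 1]
        el = sub.groupby(["site_id", "timepoint"])["el"].mean().unstack("timepoint")
        return el.reindex(columns=tps)
    if method != "pooled":
        raise ValueError(f"unknown EL aggregation method {method!r}")

    edited = (
        df.groupby(["site_id", "timepoint"])["edited"].sum().unstack("timepoint")
    )
    if pileup is None:
        covered = (
            df.groupby(["site_id", "timepoint"])["covered"].sum()
            .unstack("timepoint")
        )
        edited = edited.where(covered.notna())
    else:
        cov = pileup.merge(sample_sheet, on="sample", how="left")
        cov["covered"] = cov[list(_BASES)].sum(axis=1)
        cov_tp = (
            cov.groupby(["chrom", "pos", "timepoint"])["covered"].sum()
            .unstack("timepoint")
        )
        meta = df.drop_duplicates("site_id").set_index("site_id")[["chrom", "pos"]]
        covered = cov_tp.reindex(
            pd.MultiIndex.from_frame(meta[["chrom", "pos"]])
        )
        covered.index = meta.index
        covered = covered.reindex(columns=tps)
        edited = edited.reindex(index=covered.index, columns=tps).fillna(0.0)
        edited = edited.where(covered.notna())
    covered = covered.where(covered >= max(min_coverage_defined, 1))
    el = edited / covered
    return el.reindex(columns=tps)
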