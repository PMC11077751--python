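import numpy as np
import pandas as pd
import pytest

from editome import calling
from editome.calling import (
    FilterThresholds,
    annotate_sites,
    build_pileup,
    call_candidates,
    context_matrix,
    editing_level_by_timepoint,
    filter_cascade,
)
from editome.io_formats import COMPLEMENT, GenomeRef, SnpSet

from conftest import make_reads


def brute_force_pileup(reads, genome, trim_start, trim_end):
    """Per-read oracle: walk every read base by base."""
    counts = {}
    for r in reads.itertuples(index=False):
        L = len(r.bases)
        if L <= trim_start + trim_end:
            continue
        for off in range(L):  # off = biological offset from read start
            if not trim_start <= off < L - trim_end:
                continue
            if r.strand == "+":
                pos = r.start + off
                base = r.bases[off]
            else:
                pos = (r.start + L - 1) - off
                base = COMPLEMENT[r.bases[pos - r.start]]
            if base not in "ACGT":
                continue
            key = (r.chrom, pos, r.strand, r.sample)
            counts.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0})
            counts[key][base] += 1
    return counts


def pileup_to_dict(pu):
    out = {}
    for r in pu.itertuples(index=False):
        out[(r.chrom, r.pos, r.strand, r.sample)] = {
            "A": r.A, "C": r.C, "G": r.G, "T": r.T
        }
    return out


class TestBuildPileup:
    def test_trimming_keeps_36_of_50_positions(self, toy_genome):
        seq = toy_genome.sequences["chrT"]
        reads = make_reads([("r0", "chrT", 11, "+", seq[10:60], "s1")])
        pu = build_pileup(reads, toy_genome, trim_start=12, trim_end=2)
        assert len(pu) == 36
        assert pu["pos"].min() == 23 and pu["pos"].max() == 58

    def test_no_trimming_is_naive_tally(self, toy_genome):
        seq = toy_genome.sequences["chrT"]
        reads = make_reads([("r0", "chrT", 11, "+", seq[10:60], "s1")])
        pu = build_pileup(reads, toy_genome, trim_start=0, trim_end=0)
        assert len(pu) == 50
        assert (pu[["A", "C", "G", "T"]].sum(axis=1) == 1).all()

    def test_mismatch_at_offset_5_removed_by_trimming(self, toy_genome):
        seq = toy_genome.sequences["chrT"]
        bases = seq[10:60]
        alt = "G" if bases[5] != "G" else "C"
        bases = bases[:5] + alt + bases[6:]
        reads = make_reads([("r0", "chrT", 11, "+", bases, "s1")])
        trimmed = build_pileup(reads, toy_genome, trim_start=12, trim_end=2)
        untrimmed = build_pileup(reads, toy_genome, trim_start=0, trim_end=0)
        pos = 16  # start 11 + offset 5
        assert pos not in set(trimmed["pos"])
        row = untrimmed.loc[untrimmed["pos"] == pos].iloc[0]
        assert row[alt] == 1

    def test_minus_strand_trimming_counts_from_biological_start(self, toy_genome):
        seq = toy_genome.sequences["chrT"]
        reads = make_reads([("r0", "chrT", 11, "-", seq[10:60], "s1")])
        pu = build_pileup(reads, toy_genome, trim_start=12, trim_end=2)
        # biological start is the genomic right end (pos 60)
        assert pu["pos"].max() == 48 and pu["pos"].min() == 13

    def test_matches_per_read_oracle_including_minus_strand(self, toy_genome):
        rng = np.random.default_rng(5)
        seq = toy_genome.sequences["chrT"]
        rows = []
        for i in range(40):
            start = int(rng.integers(1, 330))
            strand = "+" if rng.random() < 0.5 else "-"
            bases = list(seq[start - 1: start + 49])
            if rng.random() < 0.7:  # sprinkle mismatches
                off = int(rng.integers(0, 50))
                bases[off] = "ACGT"[int(rng.integers(4))]
            rows.append((f"r{i}", "chrT", start, strand, "".join(bases),
                         f"s{int(rng.integers(2)) + 1}"))
        reads = make_reads(rows)
        pu = build_pileup(reads, toy_genome, trim_start=12, trim_end=2)
        assert pileup_to_dict(pu) == brute_force_pileup(reads, toy_genome, 12, 2)

    def test_short_reads_contribute_nothing(self, toy_genome):
        reads = make_reads([("r0", "chrT", 11, "+", "ACGTACGTACGTAC", "s1")])
        pu = build_pileup(reads, toy_genome, trim_start=12, trim_end=2)
        assert pu.empty


class TestCallCandidates:
    def make_pileup(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "sample", "ref",
                     "A", "C", "G", "T"],
        )

    def test_plus_strand_ag_candidate(self, toy_genome):
        pu = self.make_pileup([("chrT", 50, "+", "s1", "A", 90, 0, 10, 0)])
        out = call_candidates(pu, toy_genome)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["etype"] == "AG" and row["el"] == pytest.approx(0.10)
        assert row["covered"] == 100 and row["edited"] == 10

    def test_minus_strand_tc_reported_as_ag(self, toy_genome, toy_model):
        # genomic T->C on a minus-strand gene arrives in the pileup already
        # complemented; feed a genomic-forward pileup and let the annotation
        # flip it
        pu = self.make_pileup([("chrT", 350, "+", "s1", "T", 0, 10, 0, 90)])
        out = call_candidates(pu, toy_genome, toy_model)
        assert len(out) == 1
        assert out.iloc[0]["etype"] == "AG"
        assert out.iloc[0]["strand"] == "-"

    def test_pure_reference_yields_no_candidate(self, toy_genome):
        pu = self.make_pileup([("chrT", 50, "+", "s1", "A", 100, 0, 0, 0)])
        assert call_candidates(pu, toy_genome).empty

    def test_n_reference_skipped(self, toy_genome):
        pu = self.make_pileup([("chrT", 50, "+", "s1", "N", 90, 0, 10, 0)])
        assert call_candidates(pu, toy_genome).empty


def cand_rows(pos, alt, per_sample, strand="+", ref="A", chrom="chrT"):
    rows = []
    for sample, (cov, ed) in per_sample.items():
        rows.append(
            {"chrom": chrom, "pos": pos, "strand": strand, "ref": ref,
             "alt": alt, "etype": ref + alt, "sample": sample,
             "covered": cov, "edited": ed, "el": ed / cov if cov else np.nan}
        )
    return rows


class TestFilterCascade:
    def run(self, rows, sheet, model, snps=None, **kw):
        cand = pd.DataFrame(rows)
        return filter_cascade(cand, sheet, snps or SnpSet(set()), model,
                              FilterThresholds(**kw))

    def test_el_below_floor_fails_support(self, toy_model, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (250, 5), "T1_r2": (250, 4)})
        sites, presence, _ = self.run(rows, two_rep_sheet, toy_model)
        assert sites.empty  # pooled EL 9/500 = 0.018 < 0.02

    def test_boundary_support_passes(self, toy_model, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (250, 5), "T1_r2": (250, 5)})
        sites, _, _ = self.run(rows, two_rep_sheet, toy_model)
        assert len(sites) == 1  # EL exactly 0.02, covered 500, edited 10

    def test_splice_proximal_removed_at_3nt_kept_at_5nt(self, toy_model,
                                                        two_rep_sheet):
        # gp intron is 101-200: positions 103 (3 nt in) and 105 (5 nt in)
        rows = (cand_rows(103, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)})
                + cand_rows(105, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)}))
        sites, _, _ = self.run(rows, two_rep_sheet, toy_model)
        assert set(sites["pos"]) == {105}

    def test_snp_positions_removed(self, toy_model, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)})
        sites, _, _ = self.run(rows, two_rep_sheet, toy_model,
                               snps=SnpSet({("chrT", 50)}))
        assert sites.empty

    def test_multiallelic_removed(self, toy_model, two_rep_sheet):
        rows = (cand_rows(50, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)})
                + cand_rows(50, "T", {"T1_r1": (50, 1)}))
        sites, _, _ = self.run(rows, two_rep_sheet, toy_model)
        assert sites.empty

    def test_single_replicate_detection_removed(self, toy_model, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (50, 10)})
        sites, _, _ = self.run(rows, two_rep_sheet, toy_model)
        assert sites.empty

    def test_cascade_is_monotone_and_attrition_recorded(self, toy_model,
                                                        two_rep_sheet):
        rows = (
            cand_rows(50, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)})
            + cand_rows(65, "G", {"T1_r1": (50, 10)})
            + cand_rows(103, "G", {"T1_r1": (50, 10), "T1_r2": (50, 10)})
        )
        sites, presence, attr = self.run(rows, two_rep_sheet, toy_model)
        t1 = attr.loc[attr["timepoint"] == "T1"].set_index("stage")["n_sites"]
        assert t1["candidates"] == 3
        assert t1["both_replicates"] == 2
        assert t1["splice_proximal"] == 1
        assert t1["support"] == 1
        ns = t1.tolist()
        assert all(b <= a for a, b in zip(ns, ns[1:]))
        assert presence.loc["chrT:50:+:G", "T1"]


class TestAnnotateSites:
    def build_sites(self, pos, alt="G", strand="+"):
        return pd.DataFrame(
            [{"site_id": f"chrT:{pos}:{strand}:{alt}", "chrom": "chrT",
              "pos": pos, "strand": strand, "ref": "A", "alt": alt,
              "etype": "A" + alt, "covered": 50, "edited": 10, "el": 0.2,
              "timepoint": "T1"}]
        )

    def test_codon_change_classification(self, toy_model):
        # build a genome where CDS of gp starts at 41 with codon AAA (Lys):
        # editing position 41 (codon pos 1) -> GAA (Glu): nonsynonymous
        seq = list("A" * 400)
        genome_ns = GenomeRef({"chrT": "".join(seq)})  # AAA codons everywhere
        sites = self.build_sites(41)
        out = annotate_sites(sites, toy_model, genome_ns)
        assert out.iloc[0]["region"] == "CDS-nonsynonymous"

        # GCA (Ala) -> GCG (Ala) at codon position 3: synonymous
        seq = list("".join("GCA" for _ in range(134)))[:400]
        genome_syn = GenomeRef({"chrT": "".join(seq)})
        # CDS starts at 41; position 43 is codon position 3 of the first codon
        sites = self.build_sites(43)
        out = annotate_sites(sites, toy_model, genome_syn)
        assert out.iloc[0]["region"] == "CDS-synonymous"

    def test_region_classes(self, toy_model, toy_genome):
        for pos, expected in [(20, "5'UTR"), (250, "3'UTR"), (150, "intron")]:
            out = annotate_sites(self.build_sites(pos), toy_model, toy_genome)
            assert out.iloc[0]["region"] == expected

    def test_ambiguous_sites_excluded(self, toy_genome):
        from editome.io_formats import Transcript, TranscriptModel

        # two transcripts of one gene disagree: CDS vs intron at pos 60
        t1 = Transcript("g.t1", "g", "chrT", "+", [(11, 100)], [(41, 100)])
        t2 = Transcript("g.t2", "g", "chrT", "+", [(11, 50), (81, 100)], [])
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chrT", "start": 11, "end": 100,
              "strand": "+"}]
        )
        model = TranscriptModel(genes, {"g.t1": t1, "g.t2": t2})
        out = annotate_sites(self.build_sites(60), model, toy_genome)
        assert out.empty


class TestContextMatrix:
    def test_offset_zero_is_always_a(self):
        g = GenomeRef({"c": "CAGTACT"})
        sites = pd.DataFrame(
            [{"chrom": "c", "pos": 2, "strand": "+"},
             {"chrom": "c", "pos": 5, "strand": "+"}]
        )
        cm = context_matrix(sites, g, k=1)
        assert cm.loc[0, "A"] == 1.0
        assert cm.loc[-1, "C"] == 0.5 and cm.loc[-1, "T"] == 0.5
        assert cm.loc[1, "G"] == 0.5 and cm.loc[1, "C"] == 0.5

    def test_minus_strand_context_is_complemented(self):
        # genomic C T A: transcript strand of '-' gives T upstream of A? walk:
        # site at pos 2 ('T' genomic) on '-' strand is A; -1 neighbour is
        # genomic pos 3 complemented
        g = GenomeRef({"c": "CTA"})
        sites = pd.DataFrame([{"chrom": "c", "pos": 2, "strand": "-"}])
        cm = context_matrix(sites, g, k=1)
        assert cm.loc[0, "A"] == 1.0
        assert cm.loc[-1, "T"] == 1.0  # genomic A at pos 3 -> T on minus
        assert cm.loc[1, "G"] == 1.0  # genomic C at pos 1 -> G on minus

    def test_k0_single_column(self):
        g = GenomeRef({"c": "AAA"})
        sites = pd.DataFrame([{"chrom": "c", "pos": 2, "strand": "+"}])
        cm = context_matrix(sites, g, k=0)
        assert list(cm.index) == [0] and cm.loc[0, "A"] == 1.0

    def test_chromosome_edge_offsets_skipped(self):
        g = GenomeRef({"c": "AG"})
        sites = pd.DataFrame([{"chrom": "c", "pos": 1, "strand": "+"}])
        cm = context_matrix(sites, g, k=1)
        assert np.isnan(cm.loc[-1]).all()
        assert cm.loc[1, "G"] == 1.0


class TestEditingLevelByTimepoint:
    def test_pooled_ratio(self, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (50, 5), "T1_r2": (50, 15)})
        el = editing_level_by_timepoint(pd.DataFrame(rows), two_rep_sheet)
        assert el.loc["chrT:50:+:G", "T1"] == pytest.approx(0.20)

    def test_one_empty_replicate_contributes_nothing(self, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (10, 3), "T1_r2": (0, 0)})
        el = editing_level_by_timepoint(pd.DataFrame(rows), two_rep_sheet)
        assert el.loc["chrT:50:+:G", "T1"] == pytest.approx(0.3)

    def test_zero_coverage_is_missing_not_zero(self, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (50, 5), "T1_r2": (50, 5)})
        el = editing_level_by_timepoint(pd.DataFrame(rows), two_rep_sheet)
        assert np.isnan(el.loc["chrT:50:+:G", "T2"])

    def test_pileup_coverage_gives_zero_el_where_unedited(self, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (50, 5), "T1_r2": (50, 5)})
        pileup = pd.DataFrame(
            [
                {"chrom": "chrT", "pos": 50, "strand": "+", "sample": s,
                 "ref": "A", "A": 40, "C": 0, "G": g, "T": 0}
                for s, g in [("T1_r1", 5), ("T1_r2", 5),
                             ("T2_r1", 0), ("T2_r2", 0)]
            ]
        )
        el = editing_level_by_timepoint(pd.DataFrame(rows), two_rep_sheet,
                                        pileup=pileup)
        assert el.loc["chrT:50:+:G", "T2"] == 0.0
        assert el.loc["chrT:50:+:G", "T1"] == pytest.approx(10 / 90)

    def test_mean_method(self, two_rep_sheet):
        rows = cand_rows(50, "G", {"T1_r1": (100, 10), "T1_r2": (10, 3)})
        el = editing_level_by_timepoint(pd.DataFrame(rows), two_rep_sheet,
                                        method="mean")
        assert el.loc["chrT:50:+:G", "T1"] == pytest.approx((0.1 + 0.3) / 2)
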