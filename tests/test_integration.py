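import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editome import integration
from editome.integration import (
    adar_correlation,
    association_fisher,
    association_fisher_stratified,
    classify_dte_groups,
    classify_genes,
    correlation_category,
    pair_correlation,
    pair_sites_to_events,
    pair_summaries,
)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the same margins, summing probabilities <= the observed one."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestAssociationFisher:
    def make_flags(self, a, b, c, d):
        rows = ([{"es": True, "as_": True}] * a
                + [{"es": True, "as_": False}] * b
                + [{"es": False, "as_": True}] * c
                + [{"es": False, "as_": False}] * d)
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "table", [(10, 90, 50, 50), (10, 9, 5, 8), (3, 0, 2, 7), (20, 20, 20, 20)]
    )
    def test_p_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        res = association_fisher(self.make_flags(a, b, c, d))
        oracle = fisher_enumeration_oracle([[a, b], [c, d]])
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_all_zero_row_gives_p_one(self):
        res = association_fisher(self.make_flags(0, 0, 10, 20))
        assert res.p_value == 1.0
        assert np.isnan(res.odds_ratio)

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            es = rng.random(80) < 0.4
            asf = rng.random(80) < 0.5
            ps.append(association_fisher(
                pd.DataFrame({"es": es, "as_": asf})).p_value)
        # Fisher p is discrete and conservative; check no excess small ps
        assert np.mean(np.array(ps) <= 0.05) <= 0.07

    def test_stratified_mode_runs(self):
        rng = np.random.default_rng(1)
        flags = pd.DataFrame(
            {"es": rng.random(200) < 0.4, "as_": rng.random(200) < 0.5}
        )
        lengths = pd.Series(rng.integers(500, 5000, 200))
        out = association_fisher_stratified(flags, lengths, n_bins=5)
        assert (out["stratum"] == "pooled_MH").sum() == 1
        assert len(out) == 6


class TestPairing:
    def make_events(self, rows):
        return pd.DataFrame(
            rows, columns=["event_id", "gene_id", "type", "chrom",
                           "start", "end"]
        )

    def make_sites(self, rows):
        return pd.DataFrame(
            rows, columns=["site_id", "gene_id", "chrom", "pos", "strand"]
        )

    def test_site_inside_segment_distance_zero(self):
        events = self.make_events([("e1", "g", "IR", "c", 100, 400)])
        sites = self.make_sites([("s1", "g", "c", 250, "+")])
        out = pair_sites_to_events(sites, events)
        assert out.iloc[0]["distance"] == 0
        assert out.iloc[0]["event_id"] == "e1"

    def test_nearest_event_wins(self):
        events = self.make_events(
            [("near", "g", "EX", "c", 1120, 1270),
             ("far", "g", "EX", "c", 5000, 5150)]
        )
        sites = self.make_sites([("s1", "g", "c", 1000, "+")])
        out = pair_sites_to_events(sites, events)
        assert out.iloc[0]["event_id"] == "near"
        assert out.iloc[0]["distance"] == 120

    def test_equidistant_tie_broken_by_type_priority(self):
        events = self.make_events(
            [("a_mic", "g", "MIC", "c", 200, 212),
             ("b_ir", "g", "IR", "c", 88, 100)]
        )
        sites = self.make_sites([("s1", "g", "c", 150, "+")])
        out = pair_sites_to_events(sites, events)
        assert out.iloc[0]["event_id"] == "b_ir"  # IR outranks MIC

    def test_only_same_gene_events_considered(self):
        events = self.make_events([("e1", "other", "EX", "c", 100, 200)])
        sites = self.make_sites([("s1", "g", "c", 150, "+")])
        out = pair_sites_to_events(sites, events)
        assert out.empty

    def test_distance_equals_bruteforce_on_random_genes(self):
        rng = np.random.default_rng(2)
        ev_rows, site_rows = [], []
        for g in range(15):
            for e in range(rng.integers(1, 4)):
                start = int(rng.integers(0, 5000))
                ev_rows.append((f"g{g}e{e}", f"g{g}", "EX", "c",
                                start, start + int(rng.integers(10, 400))))
            for s in range(rng.integers(1, 5)):
                site_rows.append((f"g{g}s{s}", f"g{g}", "c",
                                  int(rng.integers(0, 6000)), "+"))
        events = self.make_events(ev_rows)
        sites = self.make_sites(site_rows)
        out = pair_sites_to_events(sites, events).set_index("site_id")
        for sid, gene, chrom, pos, strand in site_rows:
            dists = [
                0 if st <= pos <= en else min(abs(pos - st), abs(pos - en))
                for eid, g, t, c, st, en in ev_rows if g == gene
            ]
            assert out.loc[sid, "distance"] == min(dists)


class TestPairCorrelation:
    def run_one(self, el, psi):
        pairs = pd.DataFrame(
            [{"site_id": "s", "gene_id": "g", "event_id": "e",
              "event_type": "IR", "distance": 10}]
        )
        el_tp = pd.DataFrame([el], index=["s"], columns=list("ABCDE")[:len(el)])
        psi_tp = pd.DataFrame([psi], index=["e"], columns=list("ABCDE")[:len(psi)])
        return pair_correlation(pairs, el_tp, psi_tp).iloc[0]

    def test_perfect_linearity(self):
        row = self.run_one([0.1, 0.2, 0.3, 0.4, 0.5], [10, 20, 30, 40, 50])
        assert row["r"] == pytest.approx(1.0)
        assert row["category"] == "Strong" and row["sign"] == "pos"
        assert row["significant_strong"]

    def test_anti_linearity(self):
        row = self.run_one([0.1, 0.2, 0.3, 0.4, 0.5], [50, 40, 30, 20, 10])
        assert row["r"] == pytest.approx(-1.0)
        assert row["category"] == "Strong" and row["sign"] == "neg"

    def test_constant_trajectory_undefined(self):
        row = self.run_one([0.2] * 5, [10, 20, 30, 40, 50])
        assert np.isnan(row["r"]) and row["category"] == "None"

    def test_too_few_common_points_skipped(self):
        row = self.run_one([0.1, 0.2, np.nan, np.nan, np.nan],
                           [10, 20, 30, 40, 50])
        assert row["n_points"] == 2 and np.isnan(row["r"])

    @pytest.mark.parametrize(
        "r,expected",
        [(0.71, "Strong"), (0.7, "Strong"), (0.69, "Moderate"),
         (0.5, "Moderate"), (0.49, "Weak"), (0.3, "Weak"),
         (0.29, "None"), (-0.75, "Strong"), (-0.55, "Moderate"), (0.0, "None")],
    )
    def test_category_boundaries(self, r, expected):
        assert correlation_category(r) == expected

    def test_categories_partition_unit_interval(self):
        for r in np.linspace(-1, 1, 2001):
            cat = correlation_category(float(r))
            a = abs(r)
            want = ("Strong" if a >= 0.7 else "Moderate" if a >= 0.5
                    else "Weak" if a >= 0.3 else "None")
            assert cat == want


class TestPairSummaries:
    def make_pairs(self, pos_d, neg_d):
        rows = []
        for i, d in enumerate(pos_d):
            rows.append({"site_id": f"p{i}", "event_id": f"ep{i}",
                         "event_type": "IR", "distance": d, "sign": "pos",
                         "significant_strong": True})
        for i, d in enumerate(neg_d):
            rows.append({"site_id": f"n{i}", "event_id": f"en{i}",
                         "event_type": "EX", "distance": d, "sign": "neg",
                         "significant_strong": True})
        return pd.DataFrame(rows)

    def test_wilcoxon_p_matches_exact_enumeration(self):
        pos, neg = [1, 2, 3], [100, 200, 300]
        out = pair_summaries(self.make_pairs(pos, neg))
        # exact two-sided rank-sum p by enumerating rank assignments
        ranks = stats.rankdata(pos + neg)
        obs = ranks[:3].sum()
        n = 6
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean_sum = np.mean(sums)
        extreme = np.mean([abs(s - mean_sum) >= abs(obs - mean_sum) - 1e-9
                           for s in sums])
        assert out["distance_wilcoxon_p"] == pytest.approx(extreme, rel=1e-9)

    def test_identical_distances_not_significant(self):
        out = pair_summaries(self.make_pairs([5, 6, 7], [5, 6, 7]))
        assert out["distance_wilcoxon_p"] > 0.5

    def test_type_enrichment_detected(self):
        out = pair_summaries(self.make_pairs(list(range(1, 30)),
                                             list(range(100, 129))))
        ct = out["type_by_sign"]
        assert ct.loc["IR", "pos"] == 29 and ct.loc["EX", "neg"] == 29
        assert out["type_by_sign_p"] < 0.01

    def test_missing_sign_skips_summaries(self):
        out = pair_summaries(self.make_pairs([1, 2], []))
        assert "distance_wilcoxon_p" not in out


class TestClassifyGenes:
    def test_class_assignment(self):
        flags = pd.DataFrame(
            {"es": [True, False, True, False],
             "as_": [True, True, False, False]},
            index=["g1", "g2", "g3", "g4"],
        )
        out, summary = classify_genes(flags)
        assert out.loc["g1", "gene_class"] == "AS&ES"
        assert out.loc["g2", "gene_class"] == "AS&Non-ES"
        assert out.loc["g3", "gene_class"] == "Non-AS&ES"
        assert out.loc["g4", "gene_class"] == "Non-AS&Non-ES"

    def test_planted_translatable_ordering_recovered(self):
        rng = np.random.default_rng(3)
        means = {("AS&ES"): 5, ("AS&Non-ES"): 4, ("Non-AS&ES"): 3,
                 ("Non-AS&Non-ES"): 2}
        rows, counts = [], {}
        i = 0
        for (es, asf), cls in [((True, True), "AS&ES"),
                               ((True, False), "Non-AS&ES"),
                               ((False, True), "AS&Non-ES"),
                               ((False, False), "Non-AS&Non-ES")]:
            for _ in range(100):
                gid = f"g{i}"; i += 1
                rows.append({"gene_id": gid, "es": es, "as_": asf})
                counts[gid] = rng.poisson(means[cls])
        flags = pd.DataFrame(rows).set_index("gene_id")
        out, summary = classify_genes(flags, translatable=pd.Series(counts))
        s = summary.set_index("gene_class")["mean_translatable"]
        assert (s["AS&ES"] > s["AS&Non-ES"] > s["Non-AS&ES"]
                > s["Non-AS&Non-ES"])


class TestClassifyDteGroups:
    def test_set_logic_and_proportions(self):
        dte = pd.DataFrame(
            [{"gene_id": "g1", "direction": "down"},
             {"gene_id": "g2", "direction": "up"},
             {"gene_id": "g3", "direction": "down"},
             {"gene_id": "g4", "direction": "down"}]
        )
        out = classify_dte_groups(dte, dpsi_genes={"g1", "g2"},
                                  del_genes={"g1", "g3"})
        out = out.set_index("group")
        assert out.loc["dAS&dES", "n_genes"] == 1
        assert out.loc["dAS&Non-dES", "n_genes"] == 1
        assert out.loc["Non-dAS&dES", "n_genes"] == 1
        assert out.loc["Non-dAS&Non-dES", "n_genes"] == 1
        assert np.allclose(out["frac_up"] + out["frac_down"], 1.0)

    def test_empty_dte_set(self):
        out = classify_dte_groups(pd.DataFrame(columns=["gene_id", "direction"]),
                                  set(), set())
        assert out.empty

    def test_planted_down_bias_is_monotone_across_groups(self):
        rng = np.random.default_rng(4)
        p_down = {"Non-dAS&Non-dES": 0.50, "Non-dAS&dES": 0.66,
                  "dAS&Non-dES": 0.68, "dAS&dES": 0.88}
        rows, dpsi, dele = [], set(), set()
        i = 0
        for grp, p in p_down.items():
            for _ in range(400):
                gid = f"g{i}"; i += 1
                if grp.startswith("dAS"):
                    dpsi.add(gid)
                if grp.endswith("&dES"):
                    dele.add(gid)
                rows.append({"gene_id": gid,
                             "direction": "down" if rng.random() < p else "up"})
        out = classify_dte_groups(pd.DataFrame(rows), dpsi, dele)
        out = out.set_index("group")["frac_down"]
        assert (out["Non-dAS&Non-dES"] < out["Non-dAS&dES"] < out["dAS&dES"])
        assert (out["Non-dAS&Non-dES"] < out["dAS&Non-dES"] < out["dAS&dES"])


class TestAdarCorrelation:
    def test_linear_driver_gives_r_near_one(self):
        summary = pd.DataFrame(
            {"n_sites": [10, 20, 40, 80, 160]},
            index=["E13", "P0", "P6", "P21", "P42"],
        )
        expr = pd.DataFrame(
            [[1.0, 2.0, 4.0, 8.0, 16.0]],
            index=["Adarb1"], columns=summary.index,
        )
        out = adar_correlation(summary, {"RNA": expr})
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["p_value"] < 0.05

    def test_unrelated_gene_small_r_on_average(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(200):
            summary = pd.DataFrame(
                {"n_sites": rng.normal(50, 10, 5)},
                index=list("ABCDE"),
            )
            expr = pd.DataFrame([rng.normal(10, 2, 5)], index=["ctrl"],
                                columns=summary.index)
            rs.append(adar_correlation(summary, {"RNA": expr}).iloc[0]["r"])
        assert abs(np.mean(rs)) < 0.15

    def test_constant_series_flagged(self):
        summary = pd.DataFrame({"n_sites": [5, 5, 5]}, index=list("ABC"))
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["Adar"],
                            columns=summary.index)
        out = adar_correlation(summary, {"RNA": expr})
        assert out.iloc[0]["constant"] and np.isnan(out.iloc[0]["r"])

    def test_two_timepoints_rejected(self):
        summary = pd.DataFrame({"n_sites": [5, 6]}, index=list("AB"))
        expr = pd.DataFrame([[1.0, 2.0]], index=["Adar"], columns=summary.index)
        with pytest.raises(ValueError, match="insufficient"):
            adar_correlation(summary, {"RNA": expr})
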