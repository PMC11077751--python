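"""Recovery and calibration measurements against simulator ground truth.

These functions score a pipeline run (or an isolated module) against the
planted truth: filter-cascade precision/recall and contaminant leakage,
clustering recovery (adjusted Rand index), test calibration (type-I error)
and power for the differential-editing, differential-splicing and
differential-TE procedures.  They are used by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffedit, splicing, translation


def site_recovery(sites: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision/recall of the final A-to-I set and per-class leak counts."""
    a2i = sites.loc[sites["etype"] == "AG"]
    called = set(zip(a2i["chrom"], a2i["pos"]))
    called_all = set(zip(sites["chrom"], sites["pos"]))
    by_class = {
        klass: set(zip(grp["chrom"], grp["pos"]))
        for klass, grp in truth.groupby("klass")
    }
    true_pos = by_class.get("true", set())
    tp = len(called & true_pos)
    leaks = {
        klass: len(pos & called_all)
        for klass, pos in by_class.items() if klass != "true"
    }
    return {
        "n_called": len(called),
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(true_pos) if true_pos else float("nan"),
        "leaks": leaks,
        "n_leaked": sum(leaks.values()),
    }


def clustering_recovery(labels: pd.Series, truth: pd.DataFrame) -> dict:
    """Adjusted Rand index of recovered clusters vs planted families."""
    from sklearn.metrics import adjusted_rand_score

    tt = truth.loc[truth["klass"] == "true"].copy()
    tt["site_id"] = (
        tt["chrom"] + ":" + tt["pos"].astype(str) + ":" + tt["strand"] + ":G"
    )
    tt = tt.set_index("site_id")
    common = labels.index.intersection(tt.index)
    ari = adjusted_rand_score(tt.loc[common, "cluster"], labels.loc[common])
    return {"ari": float(ari), "n_clustered": int(len(labels)),
            "n_matched": int(len(common))}


def llr_type_i_error(n_sims: int = 2000, coverage: int = 50, el: float = 0.2,
                     n_per_group: int = 2, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Empirical type-I error of the beta-binomial LRT under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        k1 = rng.binomial(coverage, el, n_per_group)
        k2 = rng.binomial(coverage, el, n_per_group)
        res = diffedit.redit_llr(
            np.column_stack([k1, coverage - k1]),
            np.column_stack([k2, coverage - k2]),
        )
        rejections += res.p_value <= alpha
    return rejections / n_sims


def llr_power(n_sims: int = 300, coverage: int = 100, el1: float = 0.1,
              el2: float = 0.6, n_per_group: int = 2, alpha: float = 0.05,
              seed: int = 0) -> float:
    """Empirical power of the LRT for a planted editing-level step change."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_sims):
        k1 = rng.binomial(coverage, el1, n_per_group)
        k2 = rng.binomial(coverage, el2, n_per_group)
        res = diffedit.redit_llr(
            np.column_stack([k1, coverage - k1]),
            np.column_stack([k2, coverage - k2]),
        )
        detected += res.p_value <= alpha
    return detected / n_sims


def psi_detection(n_sims: int = 300, coverage: float = 50.0,
                  psi1: float = 30.0, psi2: float = 70.0,
                  n_per_group: int = 2, seed: int = 0) -> dict:
    """Power at a planted dPSI and false-call rate under a flat null."""
    rng = np.random.default_rng(seed)
    detected = 0
    false = 0
    cols = [f"a{i}" for i in range(n_per_group)] + \
           [f"b{i}" for i in range(n_per_group)]
    g1, g2 = cols[:n_per_group], cols[n_per_group:]
    for _ in range(n_sims):
        n = np.maximum(rng.poisson(coverage, 2 * n_per_group), 1)
        inc = np.concatenate([
            rng.binomial(n[:n_per_group], psi1 / 100),
            rng.binomial(n[n_per_group:], psi2 / 100),
        ])
        psi = pd.DataFrame([100.0 * inc / n], columns=cols, index=["e"])
        out = splicing.differential_splicing(psi, g1, g2)
        detected += bool(out.iloc[0]["significant"])
        inc0 = rng.binomial(n, 0.5)
        psi0 = pd.DataFrame([100.0 * inc0 / n], columns=cols, index=["e"])
        out0 = splicing.differential_splicing(psi0, g1, g2)
        false += bool(out0.iloc[0]["significant"])
    return {"power": detected / n_sims, "false_call_rate": false / n_sims}


def dte_benchmark(n_runs: int = 6, n_genes: int = 200, frac_planted: float = 0.1,
                  log2fc: float = 2.0, mean_count: float = 200.0,
                  dispersion: float = 0.05, seed: int = 0) -> dict:
    """Power, estimate bias and null call rate of the dTE interaction test."""
    powers, estimates, null_rates = [], [], []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        samples, rows = [], []
        for lib in ("RNA", "Ribo"):
            for tp in ("t1", "t2"):
                for r in (1, 2):
                    s = f"{tp}_r{r}_{lib}"
                    samples.append((s, lib, tp))
                    rows.append({"sample": s, "timepoint": tp,
                                 "replicate": r, "libtype": lib})
        n_pl = int(n_genes * frac_planted)
        mult = np.concatenate([np.full(n_pl, 2.0 ** log2fc),
                               np.ones(n_genes - n_pl)])
        counts = np.zeros((n_genes, len(samples)))
        npar = 1.0 / dispersion
        for j, (s, lib, tp) in enumerate(samples):
            m = np.full(n_genes, mean_count)
            if lib == "Ribo" and tp == "t2":
                m = m * mult
            counts[:, j] = rng.negative_binomial(npar, npar / (npar + m))
        cdf = pd.DataFrame(counts, columns=[s for s, _, _ in samples])
        res = translation.dte_test(cdf, pd.DataFrame(rows), ("t1", "t2"))
        res = res.set_index("gene_id")
        planted = res.loc[res.index.isin(range(n_pl))]
        nulls = res.loc[res.index.isin(range(n_pl, n_genes))]
        powers.append(planted["significant"].mean())
        estimates.append(planted["log2FoldChange"].mean())
        null_rates.append(nulls["significant"].mean())
    return {
        "power": float(np.mean(powers)),
        "mean_log2fc": float(np.mean(estimates)),
        "null_call_rate": float(np.mean(null_rates)),
    }
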