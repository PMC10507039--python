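"""Recovery studies: run the pipeline on planted synthetic data and score it.

Each study generates a dataset with the synthetic module, pushes it
through the corresponding analysis stage, and scores the result against
the planted truth. These functions back both the acceptance checks and
the reproduction script; every study is deterministic given its seed.

Problem sizes are chosen to be decisive yet desk-scale: specificity and
RNase recovery at 1,000/500 junctions, differential-expression
calibration at 2,000 genes with 20+20 samples, enrichment ranking over
100 replicate worlds, and an end-to-end run at 500 genes / 2,000
junctions / 60 samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calling, diffexp, enrichment, quantify, specificity
from .simulate import (
    SimulationConfig,
    simulate_chimeric_records,
    simulate_counts,
    simulate_gene_count_matrix,
    simulate_gene_models,
    simulate_gene_sets,
    simulate_rnase_pairs,
)


def _sub_seed(seed: int, k: int) -> int:
    # independent child seeds, kept below 2**31
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def specificity_recovery(seed: int, fold: float = 10.0) -> dict:
    """Sensitivity/precision of the JSD specificity caller against planted
    fold-``fold`` cell-type-specific junctions (20 samples per class)."""
    config = SimulationConfig(
        seed=seed, n_genes=200, n_junctions=1000, specificity_fold=fold,
        condition_split=0.0,
    )
    models, hosts = simulate_gene_models(config)
    counts, _, design, truth = simulate_counts(models, config, hosts)
    rpm = quantify.rpm_normalize(counts, design)
    scheme = specificity.CellTypeScheme.from_design(design)
    result = specificity.score_matrix(rpm, scheme)
    called = {
        j: result.specific.loc[j].idxmax()
        for j in result.specific.index[result.specific.any(axis=1)]
    }
    if fold == 1.0 or not truth.specific_junctions:
        return {
            "false_positive_rate": len(called) / len(counts),
            "n_junctions": len(counts),
        }
    tp = sum(1 for k, c in truth.specific_junctions.items() if called.get(k) == c)
    return {
        "sensitivity": tp / len(truth.specific_junctions),
        "precision": tp / len(called) if called else float("nan"),
        "n_planted": len(truth.specific_junctions),
        "n_called": len(called),
        "n_junctions": len(counts),
    }


def rnase_recovery(seed: int) -> dict:
    """Validation rate of true circles (untreated mean >= 5 RPM) and
    rejection rate of linear decoys under the RNase-R filter."""
    config = SimulationConfig(
        seed=seed, n_genes=200, n_junctions=500, condition_split=0.0,
    )
    models, hosts = simulate_gene_models(config)
    counts, linear, design, _ = simulate_counts(models, config, hosts)
    pairs, circ_keys, decoy_keys = simulate_rnase_pairs(counts, linear, config, design)
    universe = circ_keys.append(decoy_keys)
    flags = quantify.rnase_validate(universe, pairs)
    untreated_rpm = quantify.rpm_normalize(counts, design).mean(axis=1)
    expressed = untreated_rpm.index[untreated_rpm >= 5.0]
    return {
        "circ_validated_rate": float(flags[expressed].mean()),
        "decoy_rejected_rate": float(1.0 - flags[decoy_keys].mean()),
        "n_circles": len(expressed),
        "n_decoys": len(decoy_keys),
    }


def calling_recovery(seed: int) -> dict:
    """Exactness of back-splice calling against the planted junction set in
    the presence of colinear decoy records (decoy fraction 0.5)."""
    config = SimulationConfig(
        seed=seed, n_genes=150, n_junctions=300, decoy_frac=0.5,
        condition_split=0.0, baseline_mean_rpm=20.0,
        samples_per_cell_type={"DA": 2, "TCPY": 2},
        library_size_range=(300_000, 500_000),
    )
    models, hosts = simulate_gene_models(config)
    counts, _, _, truth = simulate_counts(models, config, hosts)
    records = simulate_chimeric_records(counts, models, truth, config)
    called = calling.call_junctions(records, models, min_total_reads=2)
    called_keys = {j.key for j in called}
    planted = {k for k in counts.index if counts.loc[k].sum() >= 2}
    categories_ok = all(
        j.category == truth.junction_category[j.key] for j in called
    )
    inter = len(called_keys & planted)
    union = len(called_keys | planted)
    return {
        "set_jaccard": inter / union if union else 1.0,
        "exact_match": called_keys == planted,
        "categories_match": categories_ok,
        "n_planted": len(planted),
        "n_called": len(called_keys),
        "n_records": len(records),
    }


def nb_null_type1(seed: int, n_genes: int = 2000) -> dict:
    """Type-I error of the NB Wald test at nominal 0.05 on null data
    (no planted effect, 20+20 samples, dispersion 0.1)."""
    config = SimulationConfig(
        seed=seed, samples_per_cell_type={"DA": 40}, condition_split=0.5,
        frac_de=0.0,
    )
    counts, design, _ = simulate_gene_count_matrix(config, n_genes)
    res = diffexp.nb_wald(counts, design)
    return {
        "type1_error": float((res["pvalue"] < 0.05).mean()),
        "n_genes": len(res),
    }


def nb_power(seed: int, n_genes: int = 2000) -> dict:
    """Sensitivity at BH 0.05 for planted |log2FC| = 1.5 on 5% of genes."""
    config = SimulationConfig(
        seed=seed, samples_per_cell_type={"DA": 40}, condition_split=0.5,
        frac_de=0.05, de_fold=float(2.0**1.5),
    )
    counts, design, de_genes = simulate_gene_count_matrix(config, n_genes)
    res = diffexp.nb_wald(counts, design)
    hits = res.index[res["padj"] < 0.05]
    tp = len(set(hits) & set(de_genes))
    return {
        "power": tp / len(de_genes),
        "fdr": 1.0 - tp / len(hits) if len(hits) else 0.0,
        "n_planted": len(de_genes),
        "n_genes": len(res),
    }


def enrichment_rank_study(seed: int, n_runs: int = 100) -> dict:
    """Fraction of replicate worlds in which the planted disease set has
    the smallest enrichment p-value among all sets."""
    first = 0
    for run in range(n_runs):
        config = SimulationConfig(
            seed=_sub_seed(seed, run), n_genes=400, n_junctions=300,
            condition_split=0.0, frac_specific=0.1,
            samples_per_cell_type={ct: 2 for ct in ("DA", "TCPY", "MCPY", "PBMC", "FB")},
            n_gene_sets=50, gene_set_size=50, planted_set_odds=8.0,
            enriched_cell_type="DA",
        )
        models, hosts = simulate_gene_models(config)
        _, _, _, truth = simulate_counts(models, config, hosts)
        coll = simulate_gene_sets(models, truth, config)
        query = {
            truth.junction_host[k]
            for k, c in truth.specific_junctions.items()
            if c == "DA"
        }
        universe = set(models.genes)
        res = enrichment.disease_scan({"DA": query}, coll, universe)
        if res.iloc[0]["set_name"] == truth.enriched_sets[0]:
            first += 1
    return {"rank_first_fraction": first / n_runs, "n_runs": n_runs}


def end_to_end(seed: int) -> dict:
    """Full pipeline on one synthetic world: simulate -> call -> validate ->
    specificity -> differential expression -> enrichment."""
    config = SimulationConfig(
        seed=seed, n_genes=500, n_junctions=2000,
        samples_per_cell_type={ct: 12 for ct in ("DA", "TCPY", "MCPY", "PBMC", "FB")},
        condition_split=0.5, library_size_range=(400_000, 800_000),
    )
    models, hosts = simulate_gene_models(config)
    counts, linear, design, truth = simulate_counts(models, config, hosts)
    records = simulate_chimeric_records(counts, models, truth, config)
    called = calling.call_junctions(records, models, min_total_reads=2)
    called_counts = calling.junctions_to_counts(called, list(design.index))

    pairs, circ_keys, decoy_keys = simulate_rnase_pairs(
        called_counts, linear, config, design
    )
    validated = quantify.rnase_validate(called_counts.index, pairs)

    controls = design[design["condition"] == "HC"]
    rpm = quantify.rpm_normalize(called_counts[controls.index], controls)
    scheme = specificity.CellTypeScheme.from_design(design)
    spec = specificity.score_matrix(rpm, scheme)

    host_map = pd.Series({j.key: j.host_gene for j in called if j.host_gene})
    gene_counts = diffexp.aggregate_gene_counts(called_counts, host_map)
    de = diffexp.nb_wald(gene_counts, design)

    sets = simulate_gene_sets(models, truth, config)
    query = set(host_map[spec.specific.any(axis=1).reindex(host_map.index, fill_value=False)])
    res = enrichment.disease_scan({"specific": query}, sets, set(models.genes))

    return {
        "n_called": len(called),
        "n_validated": int(validated.sum()),
        "n_specific": int(spec.specific.any(axis=1).sum()),
        "n_genes_tested": len(de),
        "n_de_bh05": int((de["padj"] < 0.05).sum()),
        "top_enriched_set": str(res.iloc[0]["set_name"]),
        "top_enrichment_p": float(res.iloc[0]["p"]),
        "planted_set_recovered": bool(
            res.iloc[0]["set_name"] == (truth.enriched_sets or [None])[0]
        ),
    }
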