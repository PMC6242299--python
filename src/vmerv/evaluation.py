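"""Recovery benchmarks of the pipeline on its own synthetic data.

Every function here regenerates data from scratch with the package's
generator, runs the corresponding analysis stage, and measures how well
the planted truth is recovered.  These are the quantities reported by
the acceptance script and asserted by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .covariation import covariation_matrix
from .inheritance import fit_inheritance_model
from .methylation import summarize_ltr_methylation
from .screen import candidate_elements, screen
from .simulate import SimulationConfig, truth_to_elements


def screen_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    threshold: float = 25.0,
    config_factory=None,
) -> dict:
    """End-to-end screen recovery over seeds at the default study conditions.

    Returns sensitivity for planted variable elements, the number of DMR
    elements leaking into the candidate list, and the false-candidate
    rate among hypermethylated elements.
    """
    if config_factory is None:
        config_factory = lambda seed: SimulationConfig(seed=seed)
    n_var_hit = n_var = n_dmr_leak = n_dmr = n_hyp_fp = n_hyp = 0
    for k in range(n_seeds):
        cfg = config_factory(base_seed + k)
        _frags, _genes, truth = simulate.generate_annotation(cfg)
        trackset = simulate.generate_methylation_tracks(truth, cfg)
        elements = truth_to_elements(truth)
        summaries = summarize_ltr_methylation(elements, trackset)
        results = screen(summaries, trackset.replicates, threshold=threshold)
        cands = candidate_elements(results)
        cls = truth.elements.set_index("id")["meth_class"]
        var_ids = set(cls.index[cls == "variable"])
        dmr_ids = set(cls.index[cls.isin(["celltype_DMR", "sex_DMR"])])
        hyp_ids = set(cls.index[cls == "hypermethylated"])
        n_var_hit += len(cands & var_ids)
        n_var += len(var_ids)
        n_dmr_leak += len(cands & dmr_ids)
        n_dmr += len(dmr_ids)
        n_hyp_fp += len(cands & hyp_ids)
        n_hyp += len(hyp_ids)
    return {
        "sensitivity": n_var_hit / n_var if n_var else float("nan"),
        "dmr_leakage": n_dmr_leak,
        "n_dmr": n_dmr,
        "hyper_false_candidate_rate": n_hyp_fp / n_hyp if n_hyp else float("nan"),
        "n_variable": n_var,
        "n_hypermethylated": n_hyp,
        "n_seeds": n_seeds,
    }


def hmc_recovery(seed: int = 0, coverage: float = 100_000.0) -> dict:
    """Recover the hydroxymethylation fraction from WGBS-vs-oxBS tracks.

    At high coverage the relative deficit of the oxBS modified signal,
    (WGBS - oxBS)/WGBS, estimates the fraction of the modified signal
    that is hydroxymethylation.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=500_000,
        element_counts={("IAP", "full_length", "hypermethylated"): 3},
        coverage=coverage,
        n_genes=5,
        hyper_sd=0.0,  # no interindividual spread, so pool composition cancels
    )
    _f, _g, truth = simulate.generate_annotation(cfg)
    trackset = simulate.generate_methylation_tracks(truth, cfg)
    elements = truth_to_elements(truth)
    summaries = summarize_ltr_methylation(elements, trackset)
    deficits = []
    pairs = 0
    for s in summaries:
        for rep_w in cfg.replicates:
            if rep_w.assay != "WGBS":
                continue
            rid_o = rep_w.id.replace("WGBS", "oxBS")
            w, o = s.means[rep_w.id], s.means[rid_o]
            if np.isfinite(w) and np.isfinite(o) and w > 0:
                deficits.append((w - o) / w)
                pairs += 1
    return {"hmc_fraction": float(np.mean(deficits)), "n_pairs": pairs}


def covariation_null(
    n_panels: int = 1000, n_individuals: int = 33, n_loci: int = 6,
    fwer: float = 0.05, seed: int = 0,
) -> dict:
    """Fraction of locus pairs flagged significant under the independence null."""
    rng = np.random.default_rng([seed, 7])
    mask = np.triu(np.ones((n_loci, n_loci), dtype=bool), k=1)
    n_sig = 0
    n_pairs = 0
    any_sig = 0
    for _ in range(n_panels):
        panel = pd.DataFrame(
            rng.uniform(0.0, 1.0, size=(n_individuals, n_loci)),
            columns=[f"locus{j}" for j in range(n_loci)],
        )
        res = covariation_matrix(panel, fwer=fwer)
        sig = res.significant.to_numpy()[mask]
        n_sig += int(sig.sum())
        n_pairs += int(mask.sum())
        any_sig += bool(sig.any())
    return {
        "pair_significance_rate": n_sig / n_pairs,
        "family_any_significant_rate": any_sig / n_panels,
        "alpha_adjusted": fwer / n_loci,
        "n_panels": n_panels,
    }


def maternal_effect_recovery(
    n_seeds: int = 100, base_seed: int = 0, beta_maternal: float = 0.5,
    n_pairs: int = 30, litters_per_pair: int = 2, pups_per_litter: int = 6,
) -> dict:
    """How often the mixed model recovers a planted maternal effect within 2 SE."""
    hits = 0
    estimates = []
    for k in range(n_seeds):
        df = simulate.generate_pedigree(
            seed=base_seed + k, n_pairs=n_pairs, litters_per_pair=litters_per_pair,
            pups_per_litter=pups_per_litter, beta_maternal=beta_maternal,
        )
        res = fit_inheritance_model(df)
        est = res.effects.loc["maternal", "estimate"]
        se = res.effects.loc["maternal", "se"]
        estimates.append(est)
        if abs(est - beta_maternal) <= 2 * se:
            hits += 1
    return {
        "coverage_2se": hits / n_seeds,
        "mean_estimate": float(np.mean(estimates)),
        "beta_true": beta_maternal,
        "n_seeds": n_seeds,
    }


def inheritance_type_i_error(
    n_datasets: int = 200, base_seed: int = 10_000, alpha: float = 0.05,
    n_pairs: int = 20, litters_per_pair: int = 2, pups_per_litter: int = 5,
) -> dict:
    """Rejection rate of the maternal effect when no effect is planted."""
    p_values = []
    for k in range(n_datasets):
        df = simulate.generate_pedigree(
            seed=base_seed + k, n_pairs=n_pairs, litters_per_pair=litters_per_pair,
            pups_per_litter=pups_per_litter,
            beta_maternal=0.0, beta_paternal=0.0, beta_sex=0.0,
        )
        res = fit_inheritance_model(df)
        p_values.append(float(res.effects.loc["maternal", "p"]))
    p = np.asarray(p_values)
    return {
        "type_i_error": float((p < alpha).mean()),
        "p_mean": float(p.mean()),
        "n_datasets": n_datasets,
    }


def calibration_on_synthetic_validation(seed: int = 0, n_validated: int = 68) -> dict:
    """Emulate threshold calibration against experimental validation.

    Scores come from a full synthetic screen; the 'experimental range'
    of a validated element is the spread (max - min) of eight freshly
    drawn individuals' latent levels plus measurement noise, in
    percentage points.  Validated elements are sampled to span the score
    range, and the smallest threshold achieving 75% precision at the
    10-point validation cutoff is returned.
    """
    from .screen import calibrate_threshold, results_to_table

    cfg = SimulationConfig(seed=seed)
    _f, _g, truth = simulate.generate_annotation(cfg)
    trackset = simulate.generate_methylation_tracks(truth, cfg)
    elements = truth_to_elements(truth)
    summaries = summarize_ltr_methylation(elements, trackset)
    results = screen(summaries, trackset.replicates)
    table = results_to_table(results).dropna(subset=["score_pp"])
    per_el = table.groupby("element_id")["score_pp"].max()
    rng = np.random.default_rng([seed, 11])
    cls = truth.elements.set_index("id")["meth_class"]
    lo, hi = cfg.variable_range
    # stratified sample across the score range, mimicking validation of a
    # subset of elements spanning low to high computational scores
    ordered = per_el.sort_values()
    pick = np.unique(np.linspace(0, len(ordered) - 1, n_validated).astype(int))
    scores, exp_ranges = [], []
    for eid in ordered.index[pick]:
        scores.append(float(per_el[eid]))
        if cls[eid] == "variable":
            individuals = rng.uniform(lo, hi, size=8)
        else:
            individuals = np.clip(rng.normal(cfg.hyper_mean, cfg.hyper_sd, size=8), 0, 1)
        noise = rng.normal(0, 1.0)  # pyrosequencing-scale measurement error, pp
        exp_ranges.append(100.0 * (individuals.max() - individuals.min()) + noise)
    t, precision = calibrate_threshold(
        np.asarray(scores), np.asarray(exp_ranges), validation_cutoff=10.0, target_precision=0.75
    )
    return {"threshold_pp": t, "precision": precision, "n_validated": len(scores)}
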