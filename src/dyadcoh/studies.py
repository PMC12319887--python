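"""Cohort-level simulation studies.

Each function simulates a seeded cohort of dyads under stated conditions,
runs the full pipeline, and performs the corresponding statistical analysis:

* :func:`ssr_contrast` — does removing the shared superficial signal lower
  band coherence? (physiological-noise inflation)
* :func:`condition_recovery` — does the stepwise mixed-model selection
  recover an injected condition-dependent coupling?
* :func:`pseudodyad_contrast` — is true-dyad coherence above the
  phase-scrambled null exactly where coupling was injected?

The cohort sizes and the scaled montage (4 long + 2 short channels) are the
package's simulation-study sizes; the generator itself defaults to the full
16-channel cap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, dyad_coherence_table, process_recording, whole_brain_means
from .protocol import ProtocolTimeline, make_protocol
from .simulate import SimulationConfig, dyad_seeds, simulate_dyad
from .stats import condition_effects, fdr_adjust, paired_onesided_test, stepwise_lrt
from .surrogate import ensemble_table, pseudodyad_ensemble
from .coherence import enumerate_pairs

#: Scaled study montage: one long channel per ROI plus the two short channels.
STUDY_SIM = SimulationConfig(n_lsc=4, n_ssc=2)
STUDY_PIPE = PipelineConfig(qc=False, chromophores=("HbO2",))


def study_sim_config(
    coupling: dict[str, float] | None = None, **overrides
) -> SimulationConfig:
    cfg = STUDY_SIM
    if coupling is not None:
        cfg = replace(cfg, coupling_strength_by_condition=dict(coupling))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ProcessedDyad:
    dyad_id: str
    timeline: ProtocolTimeline
    child_pre: "object"  # HemoTimeSeries before SSR
    mother_pre: "object"
    child_post: "object"  # after SSR (equal to *_pre when no valid SSC)
    mother_post: "object"
    ssr_applied: bool


def simulate_processed_cohort(
    n_dyads: int,
    sim: SimulationConfig = STUDY_SIM,
    master_seed: int = 0,
    n_trials: int = 2,
    task_dur: float = 120.0,
    rest_dur: float = 80.0,
    pipe: PipelineConfig = STUDY_PIPE,
) -> list[ProcessedDyad]:
    """Simulate and preprocess a cohort; each dyad gets its own seeded
    protocol order and noise streams derived from ``master_seed``."""
    dyads: list[ProcessedDyad] = []
    for i, seed in enumerate(dyad_seeds(master_seed, n_dyads)):
        timeline = make_protocol(n_trials, task_dur, rest_dur, seed=seed)
        child_rec, mother_rec, _ = simulate_dyad(sim, timeline, seed)
        c_pre, c_post, c_res = process_recording(child_rec, pipe)
        m_pre, m_post, m_res = process_recording(mother_rec, pipe)
        dyads.append(
            ProcessedDyad(
                dyad_id=f"dyad{i:03d}", timeline=timeline,
                child_pre=c_pre, mother_pre=m_pre,
                child_post=c_post, mother_post=m_post,
                ssr_applied=c_res.applied and m_res.applied,
            )
        )
    return dyads


def cohort_table(
    dyads: list[ProcessedDyad],
    use_ssr: bool = True,
    level: str = "channel",
    pipe: PipelineConfig = STUDY_PIPE,
) -> pd.DataFrame:
    """Stack per-dyad coherence tables for the whole cohort."""
    frames = []
    for d in dyads:
        child = d.child_post if use_ssr else d.child_pre
        mother = d.mother_post if use_ssr else d.mother_pre
        frames.append(
            dyad_coherence_table(
                child, mother, d.timeline, d.dyad_id, level, pipe,
                ssr_applied=use_ssr and d.ssr_applied,
            )
        )
    return pd.concat(frames, ignore_index=True)


def ssr_contrast(
    n_dyads: int = 20,
    master_seed: int = 0,
    sim: SimulationConfig | None = None,
    pipe: PipelineConfig = STUDY_PIPE,
) -> dict:
    """Band coherence with versus without superficial signal regression.

    Simulates a cohort with strongly shared systemic physiology
    (systemic_share 0.8, extracerebral gain 10), computes HbO2 whole-brain
    band WTC per dyad both ways, and runs the one-sided paired test that
    unregressed coherence exceeds regressed coherence, per condition and
    overall.
    """
    sim = sim or study_sim_config(systemic_share=0.8, extracerebral_gain=10.0)
    dyads = simulate_processed_cohort(n_dyads, sim, master_seed, pipe=pipe)
    with_ssr = whole_brain_means(cohort_table(dyads, use_ssr=True, pipe=pipe))
    without_ssr = whole_brain_means(cohort_table(dyads, use_ssr=False, pipe=pipe))
    merged = with_ssr.merge(
        without_ssr, on=["dyad_id", "chromophore", "condition"],
        suffixes=("_ssr", "_raw"),
    )
    hbo = merged[merged["chromophore"] == "HbO2"]
    per_dyad = hbo.groupby("dyad_id")[["mean_wtc_raw", "mean_wtc_ssr"]].mean()
    t, df, p = paired_onesided_test(
        per_dyad["mean_wtc_raw"].to_numpy(), per_dyad["mean_wtc_ssr"].to_numpy(),
        alternative="greater",
    )
    by_condition = {}
    for cond, sub in hbo.groupby("condition"):
        tc, dfc, pc = paired_onesided_test(
            sub["mean_wtc_raw"].to_numpy(), sub["mean_wtc_ssr"].to_numpy(),
            alternative="greater",
        )
        by_condition[cond] = {
            "t": tc, "df": dfc, "p": pc,
            "mean_difference": float((sub["mean_wtc_raw"] - sub["mean_wtc_ssr"]).mean()),
        }
    return {
        "table": merged,
        "mean_without_ssr": float(per_dyad["mean_wtc_raw"].mean()),
        "mean_with_ssr": float(per_dyad["mean_wtc_ssr"].mean()),
        "mean_difference": float(
            (per_dyad["mean_wtc_raw"] - per_dyad["mean_wtc_ssr"]).mean()
        ),
        "t": t, "df": df, "p": p,
        "by_condition": by_condition,
        "n_dyads": n_dyads,
    }


#: Coupling scenario for condition-recovery and pseudodyad studies:
#: strong coupling in both collaboration conditions, none when individual.
CONDITION_SCENARIO = {
    "individual": 0.0,
    "collaboration_screen": 0.8,
    "collaboration": 0.8,
}


def condition_recovery(
    n_dyads: int = 20,
    master_seed: int = 0,
    dyads: list[ProcessedDyad] | None = None,
    pipe: PipelineConfig = STUDY_PIPE,
) -> dict:
    """Stepwise mixed-model selection on a coupled cohort.

    Expects the condition term to be retained (LRT p < .05) with positive
    collaboration coefficients relative to the individual baseline.
    """
    if dyads is None:
        dyads = simulate_processed_cohort(
            n_dyads, study_sim_config(CONDITION_SCENARIO), master_seed, pipe=pipe
        )
    table = cohort_table(dyads, use_ssr=True, pipe=pipe)
    hbo = table[table["chromophore"] == "HbO2"].copy()
    # Whole-brain per trial: average over channel pairs, keep trial structure.
    rows = (
        hbo.groupby(["dyad_id", "condition", "trial"], sort=True)["mean_wtc"]
        .mean().reset_index()
    )
    best, history = stepwise_lrt(rows, candidate_terms=("trial", "condition"))
    effects = condition_effects(best)
    condition_lrt = next((h for h in history if h.term == "condition"), None)
    return {
        "table": rows,
        "best_fit": best,
        "history": history,
        "condition_lrt": condition_lrt,
        "condition_effects": effects,
        "dyads": dyads,
        "n_dyads": len(dyads),
    }


def pseudodyad_contrast(
    dyads: list[ProcessedDyad],
    n_iter: int = 40,
    master_seed: int = 0,
    pipe: PipelineConfig = STUDY_PIPE,
    chromophore: str = "HbO2",
) -> dict:
    """True versus phase-scrambled pseudodyad coherence, per condition.

    Whole-brain (pair-averaged) true coherence per dyad/condition is compared
    with the pseudodyad ensemble mean via one-sided paired tests; p-values
    are FDR-adjusted across conditions.
    """
    true_tab = whole_brain_means(cohort_table(dyads, use_ssr=True, pipe=pipe))
    true_tab = true_tab[true_tab["chromophore"] == chromophore]

    rows = []
    for k, d in enumerate(dyads):
        pairs = enumerate_pairs(d.child_post, d.mother_post, "channel")
        ens = pseudodyad_ensemble(
            d.child_post, d.mother_post, pairs, d.timeline,
            n_iter=n_iter, master_seed=master_seed + 7919 * k,
            chromophore=chromophore, band=pipe.band, coi_policy=pipe.coi_policy,
            dj=pipe.dj, min_period=pipe.min_period, max_period=pipe.max_period,
        )
        etab = ensemble_table(ens)
        per_cond = etab.groupby("condition")["pseudo_mean_wtc"].mean()
        for cond, val in per_cond.items():
            rows.append({"dyad_id": d.dyad_id, "condition": cond, "pseudo_mean_wtc": val})
    pseudo_tab = pd.DataFrame(rows)

    merged = true_tab.merge(pseudo_tab, on=["dyad_id", "condition"])
    results = {}
    conds = sorted(merged["condition"].unique())
    pvals = []
    for cond in conds:
        sub = merged[merged["condition"] == cond]
        t, df, p = paired_onesided_test(
            sub["mean_wtc"].to_numpy(), sub["pseudo_mean_wtc"].to_numpy(),
            alternative="greater",
        )
        results[cond] = {
            "t": t, "df": df, "p_raw": p,
            "true_mean": float(sub["mean_wtc"].mean()),
            "pseudo_mean": float(sub["pseudo_mean_wtc"].mean()),
        }
        pvals.append(p)
    adjusted = fdr_adjust(np.array(pvals))
    for cond, p_adj in zip(conds, adjusted):
        results[cond]["p_fdr"] = float(p_adj)
    return {"table": merged, "by_condition": results, "n_iter": n_iter}


def null_pseudodyad_replicates(
    n_replicates: int = 10,
    n_dyads: int = 8,
    n_iter: int = 12,
    master_seed: int = 0,
    pipe: PipelineConfig = STUDY_PIPE,
) -> dict:
    """Replicate cohorts with zero coupling everywhere: the true-versus-
    pseudodyad contrast should be non-significant (after FDR) in nearly all
    replicates."""
    null_coupling = {c: 0.0 for c in CONDITION_SCENARIO}
    clean = 0
    details = []
    for r in range(n_replicates):
        seed = master_seed + 104729 * (r + 1)
        dyads = simulate_processed_cohort(
            n_dyads, study_sim_config(null_coupling), seed, pipe=pipe
        )
        res = pseudodyad_contrast(dyads, n_iter=n_iter, master_seed=seed, pipe=pipe)
        any_sig = any(v["p_fdr"] < 0.05 for v in res["by_condition"].values())
        clean += int(not any_sig)
        details.append({c: v["p_fdr"] for c, v in res["by_condition"].items()})
    return {
        "n_replicates": n_replicates,
        "n_clean": clean,
        "fraction_clean": clean / n_replicates,
        "details": details,
    }
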