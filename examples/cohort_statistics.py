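"""Small cohort study: stepwise mixed-model selection on simulated dyads.

Simulates eight dyads with coupling injected in the collaboration conditions
only, reduces coherence tables to whole-brain per-trial means, and runs the
stepwise likelihood-ratio model sequence (null -> trial -> condition) with a
random intercept per dyad.
"""

from dyadcoh.studies import CONDITION_SCENARIO, condition_recovery

res = condition_recovery(n_dyads=8, master_seed=2025)
print(f"cohort: {res['n_dyads']} dyads, {len(res['table'])} whole-brain rows")
print("stepwise sequence:")
for h in res["history"]:
    flag = "retained" if h.retained else "dropped"
    print(f"  + {h.term:10s} X2({h.df}) = {h.chi2:6.2f}, p = {h.p:.4f}  -> {flag}")
print(f"best model: {res['best_fit'].formula}")
for level, (beta, se, p) in res["condition_effects"].items():
    print(f"  {level:22s} beta = {beta:+.4f} (SE {se:.4f}), p = {p:.2g}")
# With coupling 0.8 in both collaboration conditions and 0 in the individual
# condition, the condition term should be retained with clearly positive
# collaboration coefficients; trial carries no signal and should be dropped.
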