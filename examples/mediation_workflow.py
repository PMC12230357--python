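"""Full MR mediation workflow on a synthetic causal chain.

The chain is exposure --0.3--> mediator --0.2--> outcome with a direct
exposure->outcome effect of 0.1, so the true total effect is 0.16 and the
true mediated (indirect) effect is 0.06. The workflow screens both path
legs, fits the two-exposure multivariable model for the direct effects,
and reports the product-of-coefficients mediation summary with the
sign-dependent proportion mediated.
"""

from mrpath import RunConfig, SimConfig, run_mediation_workflow, simulate_sumstats

sim = simulate_sumstats(SimConfig(seed=3))
truth = sim.truth
print(f"truth: total = {truth.true_total:.3f},"
      f" mediated = {truth.true_mediation:.3f},"
      f" direct = {truth.true_direct:.3f}\n")

wf = run_mediation_workflow(
    sim.exposure, [sim.mediator], sim.outcome, RunConfig(seed=11, n_boot=500)
)
model = wf.models[0]
inp, res = model.inp, model.result
print(f"exposure->mediator (univariable MR): beta_A = {inp.beta_A:.3f}"
      f" (se {inp.se_A:.3f})")
print(f"mediator->outcome direct (MVMR):     beta_B = {inp.beta_B:.3f}"
      f" (se {inp.se_B:.3f})")
print(f"exposure->outcome total:             beta_C = {inp.beta_C:.3f}")
print(f"exposure->outcome direct (MVMR):     beta_C' = {inp.beta_Cprime:.3f}"
      f" (p = {inp.pval_Cprime:.3g})")
print(f"\nmediation effect beta_M = beta_A*beta_B = {res.beta_M:.3f}"
      f" [{res.ci_low:.3f}, {res.ci_high:.3f}]")
print(f"classification: {res.mediation_class}"
      f" | proportion mediated: {res.proportion:.1f}%"
      f" (denominator: {res.denominator_used} effect)")
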