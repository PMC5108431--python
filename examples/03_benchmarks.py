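"""Compare the one-step and classic screening-testing baselines.

On a single power-model cohort, the one-step method corrects over all
markers while screening-testing corrects only over the retained family —
the difference in the smallest q-values shows why screening helps.
"""

from spurgxe import make_power_design, one_step, simulate_cohort, standard_screening_testing

cohort = simulate_cohort(make_power_design(1, n_subjects=1000, n_snps=500), seed=5)

os = one_step(cohort)
st = standard_screening_testing(cohort, "marginal", retain=5)

true = set(range(5))
print(f"one-step: {len(os.tested_indices)} tests, "
      f"min q-value {os.qvalues.min():.3f}, "
      f"true SNPs significant at q<=0.1: {sorted(set(os.significant(0.1)) & true)}")
print(f"screening-testing (marginal): retained {list(st.tested_indices)}, "
      f"min q-value {st.qvalues.min():.3f}, "
      f"true SNPs significant at q<=0.1: {sorted(set(st.significant(0.1)) & true)}")
print("the same interaction signal clears the 5-test family but usually "
      "not the 500-test family")
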