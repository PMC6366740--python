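"""Measure how often a true-zero covariate trips the warning signals.

Simulates gaussian regression data with one real effect (beta = 1) and one
covariate whose true coefficient is exactly zero, fits the simple and
augmented candidate models by maximum likelihood, and screens each nested
pair.  Under the null, twice the log-likelihood gain is chi-square(1), so
the augmented model lands within 2 AIC units of the simple one in about
95% of replicates (P[chi2_1 <= 4]) and is ranked below it in about 84%
(P[chi2_1 < 2]) — the pretending-variable phenomenon the screen exists for.
"""

from scipy import stats

from upscreen import SimConfig, run_experiment

config = SimConfig(n=500, family="gaussian", true_terms={"x1": 1.0},
                   null_terms=("z1",), replicates=500, seed=7)
result = run_experiment(config)

print(f"{config.replicates} replicates, n={config.n}, family={config.family}")
print(f"  signal 1 (within 2 AIC):    {result.p_signal1:.3f}   "
      f"chi-square(1) theory: {stats.chi2(1).cdf(4):.3f}")
print(f"  signal 2 (ranked below):    {result.p_signal2:.3f}   "
      f"chi-square(1) theory: {stats.chi2(1).cdf(2):.3f}")
print(f"  signal 3 (similar log L):   {result.p_signal3:.3f}")
print(f"  signal 4 (CI covers zero):  {result.p_signal4:.3f}   nominal: 0.950")
print(f"  all four (flagged):         {result.p_full_flag:.3f}")
print(f"  true effect falsely flagged: {result.false_flag_rate:.3f}")
print()
print("Reading: the null covariate looks 'competitive' in ~95% of replicates")
print("yet is correctly flagged uninformative by the full screen ~80% of the")
print("time, while the genuine 1-SD effect is essentially never flagged.")
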