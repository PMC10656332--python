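"""A small Type-I-error experiment for the mean model on 2PLM-based nulls.

Builds a null population whose item means are exactly equal (a 2PLM base
table with the mean CMM imposed), then measures the rejection rate of the
MAEL G2 test at the 5% level over repeated multinomial samples.  Scale the
replication count up for publication-grade precision.
"""

from sparsecmm.simulation import run_type1_study

res = run_type1_study("mean", J=4, N=250, replications=300, seed=2024)
print(f"model=mean J={res.J} N={res.N} replications={res.replications}")
print(f"convergence rate : {res.convergence_rate:.3f}")
print(f"rejection rate   : {res.rejection_rate:.3f}  "
      f"(nominal 0.05, MC SE {res.mc_se_rate:.3f})")
print(f"beta true        : {res.beta_true:.4f}")
print(f"beta bias / SD   : {res.beta_bias:+.4f} / {res.beta_sd:.4f}")
print("\nA calibrated test keeps the rejection rate within Monte-Carlo error")
print("of 0.05; bias should be negligible against the SD.")
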