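"""Simulation-based residual diagnostics for the fitted mixed model.

250 response vectors are simulated from the fitted model; each observation's
scaled residual is its rank among its own simulated values. Under a correct
model these are iid uniform on [0, 1]: the Kolmogorov-Smirnov test checks
uniformity and the dispersion ratio compares observed to simulated Pearson
statistics (~1 when the Gamma variance model fits).
"""

import rnai_memory as rm

design = rm.SimulationDesign(
    strain_halflives={"JU1171": 0.7, "JU1395": 1.5, "N2": 3.0, "MY10": 5.5},
    seed=1,
)
table = rm.simulate_experiment(design)
hl = rm.halflife_table(rm.group_replicates(table), rm.schedules_of(design))
fit = rm.fit_glmm(hl[hl["status"] != "censored"], rm.GlmmSpec())

diag = rm.simulate_residual_check(fit, n_sim=250, seed=0)
print(f"KS uniformity: stat={diag.ks_stat:.3f}, p={diag.ks_p:.3f}")
print(f"dispersion ratio (observed/simulated Pearson): {diag.dispersion_ratio:.3f}")
print(f"residual range: [{diag.residuals.min():.3f}, {diag.residuals.max():.3f}]")

print(
    "\nA KS p above 0.05 and a dispersion ratio near 1 say the Gamma log-link"
    "\nmodel reproduces the spread of the half-life values. (At the gentle"
    "\n~10% coefficient of variation seen here, a gaussian fit would look"
    "\nsimilar - the families only separate when values spread more widely.)"
)

# the check has power against genuinely heavy-tailed data under a gaussian fit
import numpy as np
import pandas as pd

rng = np.random.default_rng(0)
n = 60
skewed = pd.DataFrame(
    {
        "value": np.exp(rng.normal(0.0, 1.0, size=n)),  # lognormal, heavy tail
        "strain": np.tile(["A", "B"], n // 2),
        "block": np.repeat(["X", "Y", "Z"], n // 3),
        "replicate": np.tile([1, 2], n // 2),
    }
)
bad = rm.fit_glmm(skewed, rm.GlmmSpec(family="gaussian_identity"))
diag_bad = rm.simulate_residual_check(bad, n_sim=250, seed=0)
print(f"\nlognormal data under a gaussian-identity fit: KS p={diag_bad.ks_p:.2g}")
print("The uniformity test flags the misspecified family decisively.")
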