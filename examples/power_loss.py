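"""What ignoring between-array dependence costs in statistical power.

A two-sample z-test with n replicates per group and compound-symmetric
correlation rho between all 2n responses.  The OLS analysis uses a standard
error that assumes independence; the WLS analysis uses the true covariance.
The closed-form powers (validated here against a Monte-Carlo rejection-rate
oracle) show the OLS test is conservative for rho > 0: power is lost, and
the loss grows with rho and shrinks with the effect size beta1.
"""

from jedkit import PowerScenario, mc_power_oracle, power_grid, power_ols, power_wls

s = PowerScenario(n=4, rho=0.5, beta1=1.0, alpha=0.05)
mc = mc_power_oracle(s, reps=200_000, seed=11)
print(f"scenario: n=4 per group, rho=0.5, beta1=1.0, alpha=0.05")
print(f"  OLS power (ignores dependence):  closed form {power_ols(s):.4f}, "
      f"Monte Carlo {mc['rate_ols']:.4f}")
print(f"  WLS power (models dependence):   closed form {power_wls(s):.4f}, "
      f"Monte Carlo {mc['rate_wls']:.4f}")

grid = power_grid(rhos=[0.0, 0.3, 0.6, 0.9], beta1s=[0.25, 0.5, 1.0], n=4)
print("\npower lost (WLS - OLS) by rho (columns) and beta1 (rows):")
print(grid.difference.round(3).to_string())
print(
    "\nThe deficit is 0 at rho=0 and grows with dependence for subtle "
    "effects (large effects saturate both tests near power 1) — "
    "erroneously assuming independence costs real power."
)
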