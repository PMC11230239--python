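"""Averaged dynamics: thresholds, fixed points, and stability.

Prints the closed-form alpha thresholds, the corticostriatal action-setting
fixed point, and the classified equilibrium catalogue of the symmetric rule
in the value setting on both sides of the threshold -- all without running a
single stochastic trial.
"""

from rstdp import (
    ActionSelectionConfig,
    AveragedParams,
    PlasticityRule,
    ValueEstimationConfig,
    alpha_threshold_action,
    alpha_threshold_value,
    corticostriatal_action_fixed_points,
    enumerate_equilibria,
)

print("critical alpha, action setting (N=1, r=10 s^-1): "
      f"{alpha_threshold_action(0.7, 0.02, [10.0]):.4f}")
print("critical alpha, action setting (N=2, r=(15,5)):  "
      f"{alpha_threshold_action(0.7, 0.02, [15.0, 5.0]):.4f}")
print("critical alpha, value setting (r=10 s^-1):       "
      f"{alpha_threshold_value(0.02, 10.0):.4f}")

rule = PlasticityRule("corticostriatal", lambda_rate=0.01)
params = AveragedParams.from_action_config(ActionSelectionConfig(), rule)
w1s, w2s = corticostriatal_action_fixed_points(params)
print(f"\ncorticostriatal action fixed point: (w1*, w2*) = "
      f"({w1s:.4f}, {w2s:.4f})")

for alpha in (1.0, 7.0):
    rule = PlasticityRule("symmetric", alpha=alpha, lambda_rate=0.001)
    params = AveragedParams.from_value_config(ValueEstimationConfig(), rule)
    print(f"\nsymmetric rule, value setting, alpha = {alpha:g}:")
    for eq in enumerate_equilibria("value", "symmetric", params):
        loc = ", ".join(f"{v:.3f}" for v in eq.location)
        print(f"  ({loc})  {eq.stability:16s} {eq.label}")
print()
print("Past alpha = 6 the reward-matching equilibria lose stability and the")
print("w=1 boundary point at p=0.75 becomes an attractor instead.")
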