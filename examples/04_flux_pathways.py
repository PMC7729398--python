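"""Transition pathways from net probability fluxes.

Integrated net fluxes over an activation/deactivation cycle show which
route the gating takes through the scheme and whether the cycle
retraces itself (hysteresis).
"""

from p2xkin.flux import (
    activation_deactivation_fluxes,
    hysteresis_scores,
    pathway_report,
)
from p2xkin.synthetic import default_rates

rates = default_rates()
F_act, F_deact = activation_deactivation_fluxes(rates, L=1.0,
                                                t_act=2.0, t_deact=5.0)

print("largest activation fluxes (toward O3 positive):")
for (a, b), v in sorted(F_act.items(), key=lambda kv: -abs(kv[1]))[:5]:
    print(f"  {a} -> {b}: {v:+.3f}")
print("largest deactivation fluxes:")
for (a, b), v in sorted(F_deact.items(), key=lambda kv: -abs(kv[1]))[:5]:
    print(f"  {a} -> {b}: {v:+.3f}")

G = pathway_report(F_act, threshold=0.01)
print(f"activation pathway graph: {G.number_of_edges()} edges above threshold")
top = max(hysteresis_scores(F_act, F_deact).items(), key=lambda kv: kv[1])
print(f"largest hysteresis score: {top[0][0]}-{top[0][1]} = {top[1]:.3f}")
# A score near zero means deactivation retraces activation on that rung;
# large scores mark pairs the cycle traverses in only one direction.
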