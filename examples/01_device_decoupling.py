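"""Device track: extract figures of merit and decouple a binding response.

Generates nine synthetic baseline/signal transfer-curve pairs with a known
injected perturbation (a pure 20% mobility drop, the signature of
binding-induced conformational disorder in the channel), extracts threshold
voltage and mobility from each curve, and splits the normalized current
response into its mobility and threshold-voltage terms.
"""

import biofet
from biofet import pipeline, synthetic_data as syn

baselines, signals = [], []
for d in range(9):
    spec = biofet.CurveGenSpec(true_vt=-10.0, true_mu_cm2=0.01, noise_rel=0.02,
                               seed=d, device_id=f"dev{d:02d}")
    base, sig = syn.gen_paired_transfer_curves(spec, delta_mu_rel=-0.20)
    baselines.append(base)
    signals.append(sig)

result = pipeline.run_device_track(baselines, signals)
agg = result.aggregates

print("nine-device aggregates (mean +/- SD):")
for key in ("delta_I_rel", "delta_mu_rel", "delta_vt_term"):
    a = agg[key]
    print(f"  {key:14s} {a.mean:+.3f} +/- {a.sd:.3f}  (RSD {a.rsd:.2f})")

# The injected truth was delta_mu/mu0 = -0.20 with no threshold shift, so the
# normalized response dI/I0 should sit near -0.20, the mobility term should
# recover -0.20, and the threshold term should be consistent with zero.
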