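"""Standardized mean differences and pooled inference for one indicator.

Five studies report an apnea-severity indicator at baseline and follow-up.
Each study's Hedges' g (follow-up minus baseline, so negative = the
indicator decreased) is pooled by inverse variance; the fixed/random model
choice follows the heterogeneity test (random iff p_Q < 0.05 and I^2 > 50%).
"""

from metaprofile import funnel_points, hedges_g, select_and_pool

studies = [  # (study, baseline (mean, sd, n), follow-up (mean, sd, n))
    ("S1", (34.1, 17.0, 28), (16.2, 12.1, 28)),
    ("S2", (41.6, 20.3, 35), (22.9, 15.5, 33)),
    ("S3", (28.7, 14.2, 19), (18.0, 11.7, 19)),
    ("S4", (37.9, 18.8, 52), (25.3, 16.0, 50)),
    ("S5", (30.2, 15.1, 24), (19.8, 12.9, 24)),
]
effects = [hedges_g(b, f, study_id=sid, indicator="AHI")
           for sid, b, f in studies]
for e in effects:
    print(f"{e.study_id}: g = {e.g:+.3f}  se = {e.se:.3f}")

r = select_and_pool(effects)
print(f"\npooled g = {r.pooled_g:+.3f}  95% CI [{r.ci_low:+.3f}, {r.ci_high:+.3f}]")
print(f"model = {r.model}  z = {r.z:.2f}  p = {r.p:.2e}")
print(f"heterogeneity: Q = {r.het.Q:.2f} (df {r.het.df}, p = {r.het.p_Q:.3f}), "
      f"I2 = {r.het.I2:.1f}%, tau2 = {r.het.tau2:.4f}")
print(f"=> significant {r.direction.value}" if r.significant
      else "=> no significant change")

print("\nfunnel-plot points (g vs se):")
for p in funnel_points(effects):
    print(f"  {p.study_id}: ({p.g:+.3f}, {p.se:.3f})")
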