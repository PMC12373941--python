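"""Invasion-front geometry from binary masks.

Builds masks for a control and a 'silenced' condition whose forks are 50%
shallower, profiles them, and compares deep-fork statistics.
"""

from invascope import invasion, synthetic

forks = [(60, 10, 150.0), (150, 8, 250.0), (300, 12, 120.0)]
profiles_a, profiles_b = [], []
for rep in range(3):
    mask_a, _ = synthetic.gen_invasion_mask(forks=forks, seed=rep)
    mask_b, _ = synthetic.gen_invasion_mask(
        forks=[(c, w, d * 0.5) for c, w, d in forks], seed=100 + rep
    )
    profiles_a.append(invasion.front_profile(mask_a))
    profiles_b.append(invasion.front_profile(mask_b))

p0 = profiles_a[0]
print("depth histogram (control, 100-um bins):")
print(invasion.depth_histogram(p0, 100.0).to_string(index=False))
for thr in (100.0, 200.0):
    na = invasion.count_deep_forks(profiles_a[0], thr)
    nb = invasion.count_deep_forks(profiles_b[0], thr)
    print(f"positions deeper than {thr:.0f} um: control={na}, silenced={nb}")

effect, p = invasion.compare_conditions(profiles_a, profiles_b, "mean_depth")
print(f"\nmean-depth effect (silenced - control) = {effect:+.1f} um, "
      f"exact rank-test p = {p}")
print("Shallower forks after silencing mean the stroma resists deep invasion;")
print("with 3 replicates per arm the smallest attainable two-sided p is 0.1.")
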