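"""Two-group comparison of morphometric distributions with per-1%
t-tests and a p-band heat map.

Two cohorts (n = 8 each) are simulated around a long phantom: the test
group carries a 26% cortical-area deficit confined to the diaphysis
(40-70% bone length).  A Student t-test at every 1% grid point localizes
the deficit; the p-band strip encodes significance exactly as a heat
map would colour it.
"""

from osteoslice import (PhantomSpec, percent_grid, simulate_groups,
                        ttest_profile)
from osteoslice.plotting import plot_group_profile

base = PhantomSpec(length_slices=450,
                   outer_radius_px=((0, 36.0), (449, 52.0)),
                   inner_radius_px=((0, 26.0), (449, 46.0)))
sim = simulate_groups(base, effects={"ct_ar_2d": [(40.0, 70.0, 0.74)]},
                      n_per_group=8, noise_cv=0.05, seed=0,
                      parameters=("ct_ar_2d",), grid=percent_grid(40, 80))
control, test = sim.profiles["ct_ar_2d"]
res = ttest_profile(control, test)

runs = res.significant_runs(alpha=0.05)
print("significant band(s) at p < .05:",
      ", ".join(f"{lo:.0f}-{hi:.0f}%" for lo, hi in runs))
inside = (res.grid_percent >= 45) & (res.grid_percent <= 65)
deficit = 100 * (1 - (res.mean_b[inside] / res.mean_a[inside]).mean())
print(f"recovered mid-band Ct.Ar deficit: {deficit:.1f}% (imposed: 26%)")
print("band counts:", {b: int((res.band == b).sum()) for b in
                       ("NS", "p05", "p01", "p001", "p0001")})

path = plot_group_profile(res, "scratch_group_comparison.png")
print(f"heat-map figure written to {path}")
print("\nThe significant band tracks the imposed 40-70% range while the "
      "distal cortex shows no difference - the site-specific pattern the "
      "slice-wise statistics are designed to localize.")
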