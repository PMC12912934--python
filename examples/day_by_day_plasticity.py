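"""Day-by-day trait plasticity with a Gaussian time summary.

Builds a synthetic 7-day, 4-condition experiment whose treatment effect
swells and fades (peaking near day 3), runs the per-day workflow, fits
a Gaussian to *ESPI over time, and summarizes the (g, distance) plane
with its convex hull.
"""

import numpy as np
import pandas as pd

from espi.evaluate import hull_centroid
from espi.io import ColumnMapping, load_tidy_table
from espi.pipeline import espi_time_series, fit_gaussian_time

rng = np.random.default_rng(3)
conds = {
    "ctrl": (20.0, 25.0, 100.0, 0.0),
    "warm": (24.0, 25.0, 100.0, 1.0),
    "bright": (20.0, 166.0, 100.0, 0.6),
    "rich": (20.0, 25.0, 200.0, 0.3),
}
rows = []
for day in range(1, 8):
    pulse = np.exp(-((day - 3.0) ** 2) / 3.0)  # effect peaks on day 3
    for cid, (t, l, nu, sens) in conds.items():
        mu = 100.0 + 40.0 * sens * pulse
        for v in rng.normal(mu, 8.0, 6):
            rows.append(dict(trait="ek", day=day, condition_id=cid,
                             value=v, temp=t, light=l, nutrient=nu))

groups, _ = load_tidy_table(
    pd.DataFrame(rows), ColumnMapping(env=("temp", "light", "nutrient"))
)
results = espi_time_series(groups)
print("day   pair                 g      dist   *ESPI")
for r in results:
    print(f"{r.time:>3}   {str(r.pair):<18} {r.g:6.2f} {r.distance:8.2f} "
          f"{r.espi:7.2f}")

fit = fit_gaussian_time([(float(r.time), r.espi) for r in results])
print(f"\nGaussian fit: peak *ESPI {fit.amplitude:.2f} on day "
      f"{fit.peak_time:.2f} (width {fit.width:.2f} d, rss {fit.rss:.3f})")

hull = hull_centroid([(abs(r.g), r.distance) for r in results])
print(f"(|g|, distance) hull: area {hull.area:.2f}, centroid "
      f"({hull.centroid[0]:.2f}, {hull.centroid[1]:.2f})")
print("\nThe peak day marks when the culture's traits diverged most per")
print("unit of environmental change; the hull summarizes how effect size")
print("and environmental separation co-vary across the week.")
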