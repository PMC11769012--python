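"""Tidal filtering of a single pixel's observation series.

A coastal pixel sees a mix of dry and flooded acquisitions.  Flooded
observations (MNDWI above the -0.1 open-water threshold) are removed;
a pixel flooded in more than 66% of its observations is excluded from
phenology extraction entirely.
"""

import numpy as np

from marshphen import ObservationSeries, apply_tidal_filter

days = np.array([20, 50, 80, 110, 140, 170, 200, 230, 260, 290, 320, 350])
ndvi = np.array([0.1, 0.1, 0.02, 0.3, 0.5, 0.02, 0.7, 0.65, 0.02, 0.3, 0.15, 0.1])
# three acquisitions caught the pixel under water
mndwi = np.array([-0.5, -0.5, 0.4, -0.5, -0.5, 0.4, -0.5, -0.5, 0.4, -0.5, -0.5, -0.5])

series = ObservationSeries(day_of_year=days, ndvi=ndvi, mndwi=mndwi)
result = apply_tidal_filter(series)

print(f"inundation frequency : {result.inundation_freq:.2f}")
print(f"pixel excluded       : {result.excluded}")
print(f"observations kept    : {len(result.series)} of {len(series)}")
print(f"kept days            : {result.series.day_of_year.astype(int).tolist()}")
# 3/12 flooded -> frequency 0.25 is under the 0.66 cutoff, so the pixel
# survives and only the three flooded observations are dropped.
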