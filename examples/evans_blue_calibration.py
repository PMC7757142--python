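"""Evans-blue standard curve: fit the linear portion, interpolate unknowns.

Radiance is linear in log10(nanograms) up to a saturation load; the fit
selects the linear portion automatically and unknown ROI radiances are
inverted to nanogram quantities.
"""

import pandas as pd

from fusbbb import fit_semilog, generate_eb_standards, quantify_regions

# standards with the top two levels saturated, as on an over-loaded filter paper
standards = generate_eb_standards(
    slope=100.0, intercept=5.0, noise_sd=2.0, saturation_ng=50.0, seed=3
)
cal = fit_semilog(standards)
print(f"slope {cal.slope:.1f} radiance/decade, intercept {cal.intercept:.1f}, "
      f"R^2 = {cal.r_squared:.4f}")
print(f"linear portion: standards {cal.linear_range[0]}..{cal.linear_range[1] - 1} "
      "(saturated top levels excluded)")

# interpolate two brain ROIs from their measured radiances
rois = pd.DataFrame({"region": ["focus", "rim"], "radiance": [225.0, 130.0]})
table, total = quantify_regions(rois, cal)
print(table.to_string(index=False))
print(f"total Evans blue: {total:.0f} ng")
# Each ng value is the dye load the ROI's fluorescence corresponds to on the
# calibrated curve; 'extrapolated' flags radiances beyond the standards.
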