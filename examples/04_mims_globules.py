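"""Quantify synthetic MIMS images: enrichment maps, M.A.D. and globules.

Generates ion-count images of a nucleus containing DNA-dense globules
(high ¹³C-thymidine and ³¹P, devoid of ¹⁵N-uridine), computes isotope
enrichment maps in % above natural abundance, segments the regions,
measures nuclear heterogeneity (M.A.D.), profiles a line across a globule
and runs the two-group comparison that contrasts globule-rich nuclei with
controls.
"""

import numpy as np

import geosilence as gs
from geosilence.mims import (
    R13C_NATURAL,
    R15N_NATURAL,
    detect_globules,
    enrichment_image,
    line_profile,
    mad_dispersion,
    region_mean_enrichment,
    segment_regions,
)
from geosilence.synthetic import generate_ion_images

planes, truth = generate_ion_images(n_globules=3, globule_radius_px=5, seed=2)
c_ratio = enrichment_image(planes["13C"], planes["12C"], R13C_NATURAL)
n_ratio = enrichment_image(planes["12C15N"], planes["12C14N"], R15N_NATURAL)
masks = segment_regions(planes["31P"], planes["12C14N"])

print("nuclear ¹³C (DNA) enrichment M.A.D.:",
      round(mad_dispersion(c_ratio, masks.nucleus), 1), "%")
print("region mean ¹⁵N (nascent RNA) enrichment:")
print(region_mean_enrichment(n_ratio, masks).round(1).to_string())
# nucleus ~150% above background after the uridine pulse, cytoplasm lower.

calls = detect_globules(
    c_ratio, n_ratio, planes["31P"], masks.nucleus, pixel_size_nm=100
)
print(f"\nglobules detected: {len(calls)} (3 injected)")
for call in calls:
    print(
        f"  area {call.area_um2:.2f} um^2, diameter {call.equivalent_diameter_um:.2f} um, "
        f"¹³C {call.mean_c13_enrichment:.0f}%, ¹⁵N {call.mean_n15_enrichment:.0f}%"
    )
# globules are ~1 um across, strongly ¹³C/³¹P enriched and at natural ¹⁵N
# background: condensed DNA that is not transcribed.

rows, cols = np.nonzero(truth["globules"] == 1)
cy, cx = rows.mean(), cols.mean()
profile = line_profile(
    np.nan_to_num(n_ratio.enrichment), (cy, cx - 10), (cy, cx + 10),
    width_px=3, pixel_size_nm=100,
)
center = profile["value"].iloc[len(profile) // 2]
print(f"\n¹⁵N line profile across a globule: center {center:.0f}% vs "
      f"flanks {profile['value'].iloc[[0, -1]].mean():.0f}%")

manifest = gs.run_mims_pipeline("scratch/mims_run", n_control=5, n_senescent=7, seed=1)
import pandas as pd

tests = pd.read_csv("scratch/mims_run/group_tests.tsv", sep="\t")
print("\ntwo-group comparison (5 control vs 7 globule-rich nuclei):")
print(tests.round(4).to_string(index=False))
# nuclear M.A.D. separates the groups: globules make the DNA distribution
# heterogeneous; the test choice (t vs Mann-Whitney) follows Shapiro-Wilk.
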