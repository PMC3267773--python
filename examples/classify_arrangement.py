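"""Helical-face geometry of two promoter designs.

Two GAL4 sites 21 bp center-to-center sit on the same face of the DNA
double helix; at 27 bp they sit on opposite faces.  This script builds
both arrangements and prints the azimuths, folded phases and face
calls, plus the evenness check for a three-site ~120-degree design.
"""

from helixsynergy.helix_geometry import classify_arrangement
from helixsynergy.templates import TEMPLATE_CATALOG, build_arrangement

for key in ("142", "145"):
    design = TEMPLATE_CATALOG[key]
    arrangement = build_arrangement(design, include_tata=True)
    result = classify_arrangement(arrangement)
    print(f"template {key} (spacers {design.spacers}, TATA offset {design.tata_offset} bp)")
    for site, azimuth in zip(arrangement.sites, result.azimuths):
        print(f"  {site.name:8s} center {site.center:6.1f} bp  azimuth {azimuth:6.1f} deg")
    for (i, j), fc in result.pair_classes.items():
        a, b = arrangement.sites[i].name, arrangement.sites[j].name
        phase = arrangement.phase_between(i, j)
        print(f"  {a} -- {b}: folded phase {phase:6.1f} deg -> {fc.value.value}-face")
    print()

three = build_arrangement(TEMPLATE_CATALOG["191"], include_tata=False)
result = classify_arrangement(three)
print("template 191 (three sites, ~120 deg steps): evenly spaced =", result.even)
print()
print("A folded phase below 90 deg means both factors protrude from the same")
print("side of the helix; above 90 deg they face away from each other.")
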