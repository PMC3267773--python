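"""Simulated two-GAL4-site spacer series: peaks, synergy, periodicity.

Runs the equilibrium steric-hindrance model over spacers 0-48 bp,
generates noisy triplicate luciferase data from it, and pushes the
data through the analysis stages: normalization, peak detection,
synergy ratio against the one-site reference, and the periodic fit
that recovers the helical repeat from activity data alone.
"""

from helixsynergy.activity_analysis import (
    curve_from_table,
    detect_peaks,
    fit_periodic_attenuation,
    synergy_ratio,
)
from helixsynergy.simulator import simulate_curve, simulate_template
from helixsynergy.synthetic import NoiseSpec, generate_activity_dataset
from helixsynergy.templates import single_site_template

spacers = range(0, 49, 2)

noise_free = simulate_curve(spacers)
one_site = simulate_template(single_site_template("GAL4"))
synergy = synergy_ratio(noise_free, one_site)
print("noise-free model curve:")
print("  peaks at spacers:", detect_peaks(noise_free), "bp")
print(f"  min two-site/one-site ratio: {synergy.min_ratio:.2f} (synergy: {synergy.synergy})")

table = generate_activity_dataset(
    spacers=spacers, noise=NoiseSpec(cv=0.10, n_replicates=3, seed=1)
)
curve = curve_from_table(table)
peaks = detect_peaks(curve)
fit = fit_periodic_attenuation(curve)
print("noisy triplicates (cv 10%, seed 1):")
print("  detected peaks:", peaks, "bp")
print(f"  fitted modulation period: {fit.period:.2f} bp (helical repeat estimate)")
print()
print("Peaks fall every ~10 bp because activation is maximal whenever the two")
print("activators come around to opposite faces of the helix; a ratio above 2")
print("means the pair activates more than twice the single-site level.")
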