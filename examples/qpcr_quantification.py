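"""From qPCR cycle thresholds to airborne genome concentrations.

Fits a standard curve to a calibrant dilution series, converts sample Ct
triplicates to bacterial genomes with the rRNA-operon correction
(calibrant 10 operons/genome, community average 4), and scales from the
quarter-filter aliquot and sampled air volume to copies per cubic metre.
"""

import numpy as np

from bioemit import (
    BACTERIAL_OPERONS,
    FilterSample,
    air_concentration,
    fit_standard_curve,
    quantify_genomes,
)

# dilution series: 10^1..10^6 calibrant genomes, near-perfect efficiency
log10_copies = np.arange(1.0, 7.0)
ct = -3.32 * log10_copies + 39.8
curve = fit_standard_curve(log10_copies, ct, calibrant="B. atrophaeus")
print(f"standard curve: slope {curve.slope:.2f} cycles/decade, "
      f"efficiency {curve.efficiency:.2f}, r^2 {curve.r_squared:.4f}")

sample = FilterSample(aliquot_fraction=0.25, flow_lpm=28.3, duration_h=22.2)
ct_triplicate = [26.4, 26.6, 26.5]
genomes = quantify_genomes(ct_triplicate, curve, BACTERIAL_OPERONS)
conc = air_concentration(genomes, sample)
print(f"aliquot genomes: {genomes:.3g}")
print(f"sampled air volume: {sample.air_volume_m3:.2f} m3")
print(f"airborne concentration: {conc:.3g} genomes/m3")

# The operon correction matters: without dividing 16S gene copies by the
# community-average 4 operons/genome, the genome count would be 4x too high.
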