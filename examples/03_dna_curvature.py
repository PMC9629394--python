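"""Intrinsic curvature and periodicity of a phased-A-tract satellite monomer.

Builds the 118-bp monomer with three A-tracts spaced 20 bp apart, predicts
the helical path of a 12-copy array, profiles its curvature in a 40-bp
window, and reads the periodicities out of a 1,024-point DFT.
"""

import numpy as np

from recsup import dnashape, synth

motif = synth.make_motif(118, 20, 3, seed=0)
tracts = dnashape.find_tracts(motif)
print(f"monomer: {len(motif)} bp, A-tracts at {tracts.a_tracts}")

array = motif * 12
profile = dnashape.curvature_profile(array, window=40)
print(f"mean curvature: {profile.values.mean():.2f} deg per helical turn")

spectrum = dnashape.dft_spectrum(profile.values, fs=1024)
top = sorted(np.argsort(spectrum.power)[::-1][:6])
for b in top:
    print(
        f"  bin {b:>3d}  period {dnashape.bin_to_period(int(b)):6.1f} bp  "
        f"power {spectrum.power[b]:.3f}"
    )
print(f"monomer period 118 bp -> bin {dnashape.period_to_bin(118)}")
print(f"tract alternation 60 bp -> bin {dnashape.period_to_bin(60)}")

# phase measurement demo: T-tracts offset 8 bp from the A-tracts at the
# 20-bp alternation period correspond to a 360*8/20 = 144 degree shift
a_tracts = dnashape.find_tracts(array).a_tracts
track = dnashape.TractTrack(
    a_tracts=a_tracts, t_tracts=[(s + 8, e + 8) for s, e in a_tracts]
)
shift = dnashape.tract_phase_shift(track)
print(f"A-vs-T tract phase shift at the 20-bp bin: {shift:.0f} degrees")
print(
    "# A-tracts repeated in phase with the ~10-bp helical screw compound\n"
    "# local bends into macroscopic curvature; the power spectrum shows the\n"
    "# monomer-length periodicity of that bending."
)
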