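"""Recover a diffusion coefficient with the full pipeline.

Simulates freely diffusing membrane molecules (input D = 0.3 um^2/s) under
a flat 200-um beam, detects and links spots in the rendered frames, and
fits D from the averaged MSD over lags 1-4.  The recovered value sits a few
percent below the input because trajectories are censored at the cell
edges and truncated when spot images overlap - the same artifacts seen in
real single-particle tracking.
"""

from virtucell import experiments

m = experiments.measure_membrane_mobility(seeds=(1,), duration_s=10.0)

print(f"tracks (>= 20 frames) : {m.n_tracks}")
print(f"mean tracked D        : {m.d_mean_um2_s:.3f} um^2/s  (input 0.3)")
print(f"track-survival off-rate: {m.off_rate_s:.2f} s^-1 "
      "(photobleaching 0.5/s + overlap truncation)")
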