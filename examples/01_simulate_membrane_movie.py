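"""Simulate a TIRF movie of single molecules diffusing on the cell membrane.

Runs the default membrane scenario (10x10x10 um cell, 1 molecule/um^2 at
D = 0.3 um^2/s, 33 fps) for three seconds and writes the rendered 16-bit
TIFF stack plus ground truth to ./out_membrane_movie/.
"""

from virtucell import engine, io
from virtucell.presets import scenario_preset

cfg = scenario_preset("S4", duration_s=3.0, seed=1)
result = engine.run(cfg)
manifest = io.write_outputs(result, "out_membrane_movie", truth_every=10)

print(f"frames rendered      : {result.n_frames} "
      f"({result.stack.frames.shape[1]}x{result.stack.frames.shape[2]} px)")
print(f"molecules simulated  : {result.population.n}")
print(f"photons emitted      : {result.photons_emitted}")
print(f"peak pixel count     : {result.stack.frames.max()}")
print(f"outputs              : {sorted(manifest.files)}")
# Under TIRF only the ~100 molecules on the coverslip face are bright;
# the evanescent field (depth ~135 nm) suppresses the other five faces.
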