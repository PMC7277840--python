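"""Normalize one cine loop into the fixed 10-frame representation.

Renders an AP4 clip with burned-in metadata, removes the metadata,
detects the cardiac cycle from the frame-mean intensity series, and
selects 10 equally spaced frames from one cycle (plus their average).
"""

import echoview as ev

clip = ev.render_clip(lvef=35, view=ev.ViewLabel.AP4, vendor="vendorB",
                      n_frames=80, seed=5, cycle_period=34)
clip = ev.burn_metadata(clip, seed=6)
print(f"raw clip: {clip.n_frames} frames, {clip.shape} px, "
      f"{clip.pixel_spacing:.4f} cm/px (true period: {clip.cycle_period})")

period, start = ev.detect_cycle(clip)
print(f"detected period {period} frames, cycle start at frame {start}")

fs = ev.preprocess_clip(clip)
print(f"frameset: {fs.frames.shape[0]} frames of "
      f"{fs.frames.shape[1]}x{fs.frames.shape[2]} px "
      f"(18.07 cm field), source indices {fs.source_indices.tolist()}")
print("the averaged image blurs the moving cavity boundary in proportion "
      "to the motion amplitude - that blur is the LVEF signal the EF "
      "regressor reads.")
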