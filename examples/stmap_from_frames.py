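"""Build an STMap from a frame stack, resample an unevenly sampled reference
signal to 30 Hz, and apply the training augmentations.

Run:  python examples/stmap_from_frames.py
"""

import numpy as np

from multiphys.stmap import AugmentConfig, FrameSequence, augment, frames_to_stmap, resample_30hz

# a stand-in "video": a flat skin-toned patch whose green channel pulses at
# 1.2 Hz (72 beats/min); a real pipeline would pass camera frames plus the
# face-ROI rectangle from an external detector
fps, T = 30.0, 256
t = np.arange(T) / fps
frames = np.zeros((T, 32, 32, 3))
frames[..., 0] = 150
frames[..., 1] = (120 + 6 * np.sin(2 * np.pi * 1.2 * t))[:, None, None]
frames[..., 2] = 110
frames += np.random.default_rng(0).normal(0, 1.5, size=frames.shape)
fs = FrameSequence(frames=np.clip(frames, 0, 255).astype(np.uint8), timestamps=t)

stmap = frames_to_stmap(fs, grid=(8, 8), roi=(0, 0, 32, 32))
print(f"STMap shape {stmap.shape} (rows = 8x8 ROI blocks, width = {T} frames), rate {stmap.rate:.1f} Hz")

spec = np.abs(np.fft.rfft(stmap.values[0, :, 1] - stmap.values[0, :, 1].mean()))
freqs = np.fft.rfftfreq(T, 1 / fps)
print(f"dominant frequency of row 0 (green): {freqs[np.argmax(spec)]*60:.1f} beats/min (truth 72)")

# reference vitals often arrive at a different, uneven rate
t_ref = np.sort(np.random.default_rng(1).uniform(0, T / fps, 120))
bvp_ref = np.sin(2 * np.pi * 1.2 * t_ref)
grid, bvp30 = resample_30hz(t_ref, bvp_ref)
print(f"reference signal resampled from {len(t_ref)} uneven samples to {len(grid)} samples at 30 Hz")

aug = augment(stmap, AugmentConfig(jitter_brightness=0.1, jitter_contrast=0.1,
                                   jitter_saturation=0.1, blur_sigma_range=(0.0, 1.0), seed=7))
print(f"augmented map range [{aug.values.min():.3f}, {aug.values.max():.3f}] (clipped to [0, 1]);")
print("color jitter and blur emulate camera/illumination variation for training.")
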