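"""Synthesize the species-typical FM pulse and verify its sweep.

The downward sweep mimics Pipistrellus abramus: instantaneous frequency
f(t) = f0 f1 / ((f0 - f1)(a f1 / f0)^t + (1 - a) f1) with a = 0.005,
f0 = 40 kHz, f1 = 80 kHz, t in ms; 10 ms duration.  Prints the closed-form
endpoints and the spectrogram ridge of the synthesized waveform.
"""

import numpy as np

from echodome import FMPulseSpec, compute_spectrogram, fm_instantaneous_frequency, synthesize_fm_pulse

spec = FMPulseSpec()
print(f"f(0)        = {fm_instantaneous_frequency(spec, 0.0):.2f} kHz")
print(f"f(10 ms)    = {fm_instantaneous_frequency(spec, 10.0):.2f} kHz")
print(f"asymptote   = {spec.f0_khz * spec.f1_khz / ((1 - spec.a) * spec.f1_khz):.2f} kHz")

rate = 1e6
pulse = synthesize_fm_pulse(spec, rate)
print(f"waveform: {len(pulse)} samples at {rate / 1e6:.0f} MHz, peak {np.abs(pulse).max():.3f}")

sg = compute_spectrogram(pulse, 1.0 / rate, window_length=256, hop=1024)
ridge = sg.bin_freqs[np.argmax(sg.magnitudes, axis=1)] / 1e3
for t, f in list(zip(sg.frame_times * 1e3, ridge))[::2]:
    print(f"  t = {t:6.3f} ms  ridge = {f:5.1f} kHz  closed form = "
          f"{fm_instantaneous_frequency(spec, t):5.1f} kHz")
print("\nThe ridge drops fast below 50 kHz within ~0.5 ms and flattens "
      "toward the 40.2 kHz terminal frequency, as in the pipistrelle call.")
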