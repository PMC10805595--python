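"""Compare all five targets' echoes via log-spectral distortion.

Simulates the impulse response of every variant in the standard scene at
dx = 2 mm, then computes the surface- and occlusion-component LSD of each
edit against the trained target T1.  The discrimination experiments found
performance tracking the occlusion component: edits that alter the hidden
back structure strongly (T2 back half removed, T5 front hole plugged --
no interior echo path) separate well; plugging the back hole (T3) or
smoothing the texture (T4) perturbs the occlusion echo far less.
Takes a couple of minutes.
"""

from echodome import DomeSpec, SceneCache, component_lsd, target_impulse_response

DX = 2.0
spec = DomeSpec()
cache = SceneCache()

irs = {
    v: target_impulse_response(spec.with_variant(v), dx=DX, cache=cache)
    for v in ("T1", "T2", "T3", "T4", "T5")
}

print(f"{'probe':5s} {'surface LSD':>12s} {'occlusion LSD':>14s}")
for v in ("T2", "T3", "T4", "T5"):
    r = component_lsd(irs[v], irs["T1"])
    print(f"{v:5s} {r.surface_lsd:10.2f} dB {r.occlusion_lsd:12.2f} dB")
print("\nHigher occlusion-component LSD corresponded to easier "
      "discrimination from T1 in the behavioural tests.")
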