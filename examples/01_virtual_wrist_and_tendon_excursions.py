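"""Build the virtual tendon-driven wrist and record actuator profiles.

Constructs the default left-arm model (two rods joined by a universal
joint, five tendons routed from fixed epicondyle exit points to the base of
the hand segment), commands a 50 deg flexion, and records the tendon
excursions the actuators would have to reproduce.
"""

import numpy as np

from wristsim import build_default_wrist, generate_motion_path, record_excursion_profile

model = build_default_wrist("left")
print("tendon -> actuator axis (left arm):", model.axis_map)

path = generate_motion_path("flexion", amplitude_deg=50.0, n_frames=200, fps=50.0)
profile = record_excursion_profile(model, path)

peak_frame = int(np.argmax(path.fe_deg))
print(f"\ncommanded flexion peaks at {path.fe_deg[peak_frame]:.1f} deg "
      f"(frame {peak_frame} of {len(path)})")
print("actuator displacement at the peak (mm, + = tendon reeled in):")
for t in model.tendons:
    axis = model.axis_map[t.name]
    print(f"  {t.name:5s} axis {axis}: {profile[peak_frame, axis - 1]:+7.2f}")

# Flexors (FCR, FCU) shorten during flexion -> positive displacements;
# extensors pay out.  All excursions stay well inside the 80 mm travel.
print(f"\nlargest |excursion| anywhere: {np.abs(profile).max():.2f} mm (travel 80 mm)")
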