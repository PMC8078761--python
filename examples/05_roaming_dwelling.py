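"""Posture-scale roaming/dwelling analysis on simulated kinematics.

Simulates a worm alternating between roaming (fast, straight, coherent
body waves) and dwelling (slow, turny), segments the states with the
two-state Gaussian HMM, and counts complete body waves per state.
"""

import numpy as np

from coilpose import behavior as bh

rng = np.random.default_rng(0)
fps = 30.0
duration_s = 2400.0
n = int(duration_s * fps)
t = np.arange(n) / fps

# two-state behavior: switch every ~5 minutes on average
state = np.zeros(n, dtype=int)
for i in range(1, n):
    state[i] = 1 - state[i - 1] if rng.random() < 1 / (300 * fps) else state[i - 1]

# centroid trajectory: speed and heading noise depend on the state
speed = np.where(state == 1, 25.0, 3.0) / fps
heading = np.cumsum(np.where(state == 1, 0.01, 0.12) * rng.standard_normal(n))
centroid = np.cumsum(speed[:, None] * np.column_stack([np.cos(heading), np.sin(heading)]), axis=0)

kin = bh.centroid_kinematics(centroid, fps)
hmm = bh.fit_roam_dwell(kin, seed=0)
frac_roam = (hmm.states == bh.ROAM).mean()
print(f"windows classified roaming: {frac_roam:.2f} "
      f"(simulated ground truth {state.mean():.2f})")
print("transition matrix (10 s windows):")
print(np.round(hmm.transition_matrix, 3))

# body wave: faster phase advance while roaming
wave_freq = np.where(state == 1, 0.45, 0.05)
phi = np.unwrap(2 * np.pi * np.cumsum(wave_freq) / fps + 0.01 * rng.standard_normal(n))
a1, a2 = 5 * np.cos(phi), 5 * np.sin(phi)
phi_est, omega = bh.phase_velocity(a1, a2, fps)
waves = bh.count_body_waves(phi_est, omega, fps)
roam_frames = state == 1
events_in_roam = roam_frames[waves["event_frames"]].sum()
print(f"\ncomplete body waves: {waves['event_frames'].size} "
      f"({events_in_roam} during roaming)")

print(
    "\nThe HMM separates the classic two on-food states from 10 s windowed "
    "centroid speed and angular speed; the body-wave count (peaks of "
    "cos(phi) within constant-sign phase-velocity runs) shows that coherent "
    "full-body locomotion waves belong almost entirely to the roaming state."
)
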