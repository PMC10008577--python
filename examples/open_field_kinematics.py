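"""Analyse one open-field pose recording end to end.

Simulates a 2-minute overhead pose track (body + head, 30 fps) with
three latent speed states and injected turning episodes, then runs the
full kinematic chain: likelihood-gated spline cleaning, frame-to-frame
speed, 3-state hidden-Markov segmentation of the log-speed profile,
novel-object proximity over the final epoch, and egocentric
turning-event detection with left/right bias.
"""

from pawbias import (
    TrajectoryGenConfig,
    angular_differences,
    approach_turning_bias,
    clean_trajectory,
    compute_speed,
    detect_turnings,
    gen_trajectory,
    heading_series,
    object_proximity,
    segment_states,
    turning_bias,
)

config = TrajectoryGenConfig(
    duration_s=120.0, object_epoch_s=30.0, turn_rate=(0.0, 0.01, 0.02), seed=13
)
raw, truth = gen_trajectory(config)
traj = clean_trajectory(raw, likelihood_threshold=0.9, smoothing=4.0)

profile = compute_speed(traj)
print(f"frames: {traj.n_frames}, average speed: {profile.mean:.2f} px/frame")

segmentation = segment_states(profile, seed=0)
for state, occupancy in segmentation.occupancy.items():
    true_occ = truth.occupancy()[state]
    print(f"  {state:<9} occupancy {occupancy:.3f}  (generator truth {true_occ:.3f})")

proximity = object_proximity(traj)
print(
    f"object epoch: mean distance {proximity.mean_distance:.0f} px, "
    f"time near object {proximity.proportion_near:.1%}"
)

events = detect_turnings(angular_differences(heading_series(traj)))
print(
    f"turning events: {len(events)} detected ({len(truth.events)} injected), "
    f"left-turn bias {turning_bias(events):.2f}"
)
print(f"approach-phase bias: {approach_turning_bias(events, traj):.2f}"
      if events else "no approach-phase events")
print(
    "\nOccupancies describe how the session splits into resting/marginal/running;"
    "\na bias far from 0.5 would indicate a lateralized turning tendency."
    "\nNote: tracking noise adds apparent movement during rest, so decoded"
    "\noccupancies shift slightly toward faster states relative to truth;"
    "\ngroup contrasts are unaffected since both groups share the noise floor."
)
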