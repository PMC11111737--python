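"""Dwell-based target selection and the boundary-distance error metric.

Holding the gaze inside a target's collider for 1.8 s triggers its event;
leaving the collider resets the timer.  Gaze error is the distance to the
visible disc's boundary divided by the screen width, so any gaze on the
visible target counts as error-free.
"""

from instantgaze import (
    DwellState,
    InteractiveTarget,
    ScreenGeometry,
    ScreenPoint,
    error_to_degrees,
    gaze_error,
    step_dwell,
)

screen = ScreenGeometry()  # 800 x 372 px, 176 mm wide, viewed from 310 mm
target = InteractiveTarget.at((120.0, 40.0), screen, event_id="play-button")
print(f"target: visual radius {target.visual_radius:.0f} px,"
      f" collider {target.collider_radius:.0f} px")

state = DwellState()
t = 0.0
for step in range(1, 100):
    t = step * 0.1
    gaze = ScreenPoint(125.0, 38.0)  # steady fixation near the target centre
    state, record = step_dwell(state, gaze, target, dt=0.1, time_s=t)
    if step in (5, 10, 15):
        print(f"  t={t:.1f}s  dwell={state.dwell_elapsed:.1f}s"
              f"  visual size {100*state.shrink_fraction:.0f}%")
    if record:
        print(f"  t={t:.1f}s  event '{record.event_id}' triggered")
        break

for gx in (120.0, 190.0, 240.0):
    e = gaze_error(ScreenPoint(gx, 40.0), target, screen)
    print(f"gaze at x={gx:5.0f}: error {100*e:.2f}% of screen width"
          f" = {error_to_degrees(e, screen):.2f} deg")
print("Errors are zero anywhere on the visible disc and grow with the"
      " distance beyond its boundary.")
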