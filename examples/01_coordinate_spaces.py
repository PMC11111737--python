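"""Build the six eye-feature representations from one raw fixation.

A fixation measurement is a pupil centre (x, y) and an eye corner (m, n) in
video-image pixels.  The six coordinate spaces differ in what the pupil and
corner are referenced to; the local-relative space indexes both to their own
first recorded positions, which removes per-subject anatomy and common-mode
head shifts.
"""

from instantgaze import RawObservation, SpaceKind, capture_origin, make_feature

first = RawObservation(pupil_x=120.0, pupil_y=-40.0, corner_m=90.0, corner_n=-45.0)
origin = capture_origin(first)

later = RawObservation(pupil_x=131.5, pupil_y=-33.0, corner_m=93.0, corner_n=-44.0)

print(f"origin (first fixation): pupil=({origin.x0}, {origin.y0})"
      f" corner=({origin.m0}, {origin.n0})\n")
print(f"{'space':<17}{'e1':>9}{'e2':>9}{'e3':>9}{'e4':>9}")
for space in SpaceKind:
    f = make_feature(space, later, origin)
    print(f"{space.value:<17}{f.e1:>9.2f}{f.e2:>9.2f}{f.e3:>9.2f}{f.e4:>9.2f}")

print(
    "\nThe global rows keep the absolute pupil/corner positions (they encode"
    "\nwho the subject is); the local_relative row keeps only the change of"
    "\nthe pupil-corner vector since the first fixation (e1, e2) and the head"
    "\nshift since the first fixation (e3, e4)."
)
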