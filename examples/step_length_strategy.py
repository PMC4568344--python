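"""Pick the step length that makes a given descent energetically free.

Inverts the optimal-gradient relation: for each slope on a route profile,
report the step parameter k and step length (for a 0.9 m leg) at which the
descent exactly pays for the centre-of-mass lift.
"""

from gradewalk import BodyParams, recommend_step_length

body = BodyParams(leg_length=0.9)

for pct in (-6, -9, -10, -12, -15, 0):
    advice = recommend_step_length(pct / 100.0, body)
    if advice.target_k is None:
        print(f"{pct:+4d}%  {advice.status}")
    else:
        flag = "comfortable" if advice.within_comfort else (
            f"uncomfortable -> clamp to k={advice.clamped_k}"
        )
        print(f"{pct:+4d}%  k={advice.target_k:5.3f}  "
              f"step={100 * advice.step_length:5.1f} cm  {flag}")

# Gentle slopes call for short steps (high k), steep ones for long steps;
# -10% maps to k = 1.30 (a 69 cm step, well inside the comfortable range
# k = 1.35 +/- 0.20). Beyond about -13% the required step exceeds the leg
# length (k < 1) and the strategy stops being practical, and uphill there
# is no step length that cancels the oscillation cost at all.
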