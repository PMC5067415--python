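"""Learned meter: additive expectation strengths and the loud rest.

Enculturates on generated 4/4 rhythm corpora, prints the combined
expectation strength at each eighth-note position after a downbeat, and
detects the 'loud rest' in a rock pattern whose third beat is missing.
"""

from idyot import (
    METER_44,
    detect_loud_rests,
    meter_expectation_profile,
    rock_pattern_onsets,
)

UNIT = 240  # eighth note in ms (125 bpm quarter)
profile = meter_expectation_profile(
    METER_44, (1.0, 0.9, 0.8, 0.6), seed=7, n_corpora=6
)

names = {8: "DOWNBEAT", 4: "mid-bar beat", 2: "beat", 6: "beat"}
print("eighth  strength")
for p in range(1, 9):
    s = profile.combined[p * UNIT // profile.grid.quantum_ms]
    label = names.get(p, "offbeat")
    print(f"  {p}     {s:5.2f}   {label}")

rock = rock_pattern_onsets(unit_ms=UNIT)
flagged = detect_loud_rests(profile, rock)
positions = [b * profile.grid.quantum_ms / UNIT for b in flagged]
print(f"\nrock pattern onsets (eighths): {[o // UNIT for o in rock]}")
print(f"loud rests flagged at eighth positions: {positions}")
print("The silent mid-bar of measure 1 is the one strongly expected beat")
print("with no event: the expectation violation a listener feels there.")
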