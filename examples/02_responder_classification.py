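"""ROPE + HDI classification of one participant's post-exercise change.

A participant whose central systolic pressure rose 10 mmHg (mean of the 15-
and 30-min deltas) is classified against a null band of +/-3.6 mmHg (20% of
an 18 mmHg baseline SD), with measurement error folded in as a normal
posterior of scale TE * sqrt(2).
"""

from pehresponse import classify_participant, rope_from_sd, technical_error

rope = rope_from_sd(baseline_sd=18.0, fraction=0.2)
print(f"ROPE: {rope.lower:+.2f} to {rope.upper:+.2f} mmHg")

for cv, note in [(0.01, "individual duplicate-measurement CV ~1%"), (0.05, "group CV 5%")]:
    te = technical_error(cv, baseline_mean=101.0)
    call = classify_participant(delta=10.0, te=te, rope=rope, seed=42)
    print(
        f"delta +10.0, TE {te:4.2f} mmHg ({note}):\n"
        f"  89% HDI [{call.hdi.lower:+6.2f}, {call.hdi.upper:+6.2f}], "
        f"{100 * call.pct_in_rope:5.1f}% of HDI in ROPE -> {call.label.value}"
    )

# The first call is a decisive hypertensive responder (<1% of the HDI inside
# the null band); with the much wider group-CV posterior the same delta is
# undecidable.
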