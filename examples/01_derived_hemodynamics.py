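"""Derived hemodynamic quantities from one supine tonometry session.

Builds a single measurement at typical baseline values and prints every
derived pressure plus the session TRIMP loads.
"""

from pehresponse import (
    Condition,
    SessionMeasurement,
    Timepoint,
    cfpwv,
    derive_panel,
    high_session_plan,
    hrr1,
    moderate_session_plan,
    trimp,
)

m = SessionMeasurement(
    participant_id="CAD001",
    condition=Condition.MOD,
    timepoint=Timepoint.PRE,
    hr=60,
    bsbp=112.0,  # brachial systolic, mmHg
    bdbp=70.0,  # brachial diastolic, mmHg
    csbp=101.0,  # central (carotid-derived) systolic, mmHg
)
panel = derive_panel(m)
print(f"MAP           {panel.map:6.1f} mmHg   (2/3 diastolic + 1/3 systolic)")
print(f"amplification {panel.amplification:6.1f} mmHg   (brachial - central systolic)")
print(f"brachial PP   {panel.bpp:6.1f} mmHg")
print(f"central PP    {panel.cpp:6.1f} mmHg   (central systolic - shared diastolic)")

# central arterial stiffness from a taped carotid-femoral distance and the
# foot-to-foot pulse transit time (the 0.8 path correction is the default)
print(f"cfPWV         {cfpwv(0.80, 0.080):6.1f} m/s")
print(f"HRR1          {hrr1(130, 112):6.1f} beats/min (peak minus 1-min recovery HR)")

# session loads: aerobic minutes weighted by heart-rate zone + sets x reps x load
for name, plan in [("moderate", moderate_session_plan()), ("high-intensity", high_session_plan())]:
    print(f"TRIMP {name:>14}: aerobic {trimp(plan).aerobic:.0f} zone-weighted minutes")
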