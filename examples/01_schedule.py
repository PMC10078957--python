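"""Generate and validate the default electrotactile stimulation schedule.

Six blocks of 300 stimuli, each split into five sub-blocks of 60, are
delivered pseudo-randomly to the dorsal (D) and volar (V) forearm sites:
25-35 stimuli per site per sub-block, never more than 3 in a row at the
same site, 700 ms apart, with the attended site alternating per block.
"""

from serpbci.protocol import ProtocolConfig, generate_schedule, validate_schedule

schedule = generate_schedule(ProtocolConfig(seed=42))
df = schedule.to_frame()

print(f"total stimuli:        {len(df)}")
print(f"per location:         {dict(df.groupby('location').size())}")
print(f"per block:            {dict(df.groupby('block').size())}")
print(f"attended, block 1-6:  {list(df.groupby('block').attended_location.first())}")

report = validate_schedule(schedule)
for check in report.checks:
    print(f"  {check.name:24s} {'ok' if check.passed else 'FAIL ' + check.detail}")

# 1,800 stimuli, 900 per site, alternating attention: one full session's
# worth of events, each later yielding one 500 ms EEG epoch.
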