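"""Minute-epoch streams to person-level compositions.

Generates ten days of minute-level wrist counts for one participant,
classifies each worn wake minute by the counts/min cut-points
(<2000 SB, 2000-7499 LPA, >=7500 MVPA; the sleep flag wins), filters days
to >= 16 h wear, and averages >= 4 valid days into a 1440-min composition.
"""

from timecoda import MinuteSimConfig, simulate_minute_stream
from timecoda.epochs import process_epochs

cfg = MinuteSimConfig(n_days=10, nonwear_gap_rate=2.0, seed=7)
stream = simulate_minute_stream(cfg, participant_id="P001")
print(f"{len(stream)} epochs over {cfg.n_days} days; "
      f"sleep window spans {cfg.sleep_minutes_per_day} min/night")

participants, exclusions = process_epochs(stream)
for line in exclusions:
    print("excluded:", line)
print(participants.round(1).to_string(index=False))
# The composition sums to 1440: non-wear time is excluded and the day is
# proportionally rescaled, so the four behaviors close the 24-h day.
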