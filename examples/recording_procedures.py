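"""Turn a raw behavioral event log into session scores three ways.

A 10-minute observation with three momentary occurrences and two sustained
episodes, summarized by frequency, duration and interval recording.
"""

from scedbehave import EventLog, summarize_duration, summarize_frequency, summarize_interval

log = EventLog(
    duration=600,  # seconds
    events=(
        95.0,          # instant occurrences
        130.0,
        310.0,
        (200, 260),    # sustained episodes (onset, offset)
        (400, 470),
    ),
)

print("frequency:", summarize_frequency(log), "occurrences")
print("duration: ", summarize_duration(log), "s of behavior")
for mode in ("partial", "whole", "momentary"):
    p = summarize_interval(log, interval_length=60, mode=mode)
    print(f"interval ({mode:9s}): {p:.2f} of 60-s bins scored")

# Partial-interval scores a bin if the behavior touches it at all, whole-
# interval only if the behavior fills it, momentary sampling only if the
# behavior is occurring at the bin's endpoint — so whole <= partial always.
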