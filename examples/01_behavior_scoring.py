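"""Score one Go/NoGo block: outcomes, d-prime, mean reaction time.

Simulates a standard 180-trial block (20% NoGo) with a 96% hit rate
and 20% false-alarm rate, then classifies every trial and summarizes
performance the way a participant-by-condition analysis would.
"""

from mobikit import BehaviorSimConfig, simulate_behavior
from mobikit.behavior import classify_trials, dprime, mean_rt, outcome_counts

events = simulate_behavior(BehaviorSimConfig(seed=42))
trials = classify_trials(events, response_window=(100, 1000))
counts = outcome_counts(trials)

d = dprime(counts["Hit"], counts["Miss"], counts["FalseAlarm"],
           counts["CorrectRejection"])
rt = mean_rt(trials)

print(f"trials scored      : {len(trials)}")
print(f"outcome counts     : {counts}")
print(f"d-prime (corrected): {d:.3f}")
print(f"mean RT over Hits  : {rt:.1f} ms")
print()
print("d' is z(hit rate) - z(false-alarm rate) with a log-linear")
print("correction; the RT mean uses Hits only, never false alarms.")
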