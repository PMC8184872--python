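"""Build and validate the randomised session schedule.

The session crosses tool-end congruency (head / handle / control) with
four image-to-cue SOAs, plus no-saccade catch trials: 840 trials in 10
blocks.  The validator returns violations as data, so an empty report
means the schedule satisfies every count and timing identity.
"""

from collections import Counter

from toolgaze import DesignParams, build_schedule, validate_schedule

params = DesignParams(rng_seed=1)
schedule = build_schedule(params)

counts = Counter(t.tool_end for t in schedule)
print(f"trials: {len(schedule)} in {params.n_blocks} blocks")
print(f"per condition: {dict(counts)}")
print(f"violations: {validate_schedule(schedule, params)}")

t = schedule[0]
print(f"first trial: {t.tool_end}/{t.orientation}, SOA {t.soa_ms} ms, "
      f"{t.cue_color} cue -> saccade {t.saccade_direction}")
print(f"  epochs (ms): image {t.image_on}, cue {t.cue_on}, "
      f"off {t.image_off}, end {t.trial_end}")
# The cue always follows image onset by the SOA; the trial is 2 s long
# regardless of SOA, so the return phase absorbs the timing difference.
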