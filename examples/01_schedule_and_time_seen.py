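"""Build one pair's game schedule and inspect the time-seen covariate.

A pair plays 8 rounds (4 turns) over a 10-item shortlist drawn from the
25-item pool; one item is swapped in before rounds 3, 5 and 7.  ``time_seen``
counts the distinct turns in which the pair has seen an item, which is the
covariate separating item-specific novelty from game-level fatigue.
"""

from symsig import DEFAULT_ITEMS, build_schedule, signal_records

schedule = build_schedule(DEFAULT_ITEMS, seed=1)
print("participants:", schedule.participants)
print("replacements (round, removed, added):")
for entry in schedule.replacement_log:
    print("  ", entry)

records = signal_records(schedule)
end_turn3 = records[records["round"] == 6]
intro = records.groupby("item")["turn"].min()
print("\nend of turn 3: item, turn introduced, time seen")
for row in end_turn3.itertuples():
    print(f"  {row.item:20s} introduced turn {intro[row.item]}  time_seen {row.time_seen}")
# Items present since turn 1 show time_seen 3; later arrivals 2 or 1.
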