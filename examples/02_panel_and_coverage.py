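"""From raw observation tables to episode coverage summaries.

Builds the per-participant daily panel from cap events + weekly surveys,
classifies every CAS episode under the 3-days-before / 2-days-after dosing
rule, and prints the per-period coverage summary alongside observed-day
descriptives.
"""

import prevently as pv

cohort = pv.simulate_cohort(pv.SimConfig(n_participants=30, followup_days=220, seed=7))
metas = [
    pv.ParticipantMeta(r.participant_id, r.enrolment_date, r.end_date)
    for r in cohort.participants.itertuples()
]
panel = pv.build_cohort_panel(cohort.cap_events, cohort.weekly_surveys, metas)

stats = pv.descriptive_stats(panel)
print("observed-day descriptives (denominators are observed days only):")
print(stats.round(2).to_string(index=False))

episodes = pv.classify_episodes(panel, pv.CoverageRule(days_before=3, days_after=2))
summary = pv.coverage_summary(episodes)
print("\nepisode coverage by period:")
print(summary.round(1).to_string(index=False))

# percent_covered is the share of assessed CAS episodes flanked by doses on
# all three preceding and both following days; unassessable episodes (window
# extends past the observed panel) are excluded from the denominator.
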