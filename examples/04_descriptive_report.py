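"""Descriptive tables on the reconstructed reference population.

The reference deployment's aggregate tables (24,818 sessions) are rebuilt as
a session-level corpus, and the tabulation functions recompute the published
marginals from it: struggle-topic shares, EAP inflow/outflow percentages,
resources per session, and the demographics of disclosing users.
"""

import peersent as ps
from peersent.datasets import study_population_corpus
from peersent.sessions import split_cohorts

corpus = study_population_corpus()
print(f"sessions: {len(corpus)}")

topics = ps.topic_distribution(corpus)
print("\ntop struggle topics:")
for _, row in topics.head(5).iterrows():
    print(f"  {row.topic:>26}: {row['count']:>6} ({row.percent:.2f}%)")

inflow = ps.eap_flow_table(corpus, "inflow").set_index("topic")
outflow = ps.eap_flow_table(corpus, "outflow").set_index("topic")
print(f"\nEAP inflow:  {inflow.loc['overall', 'percent']:.2f}% of sessions "
      f"(anxiety tops the per-topic rates at {inflow.loc['anxiety', 'percent']:.2f}%)")
print(f"EAP outflow: {outflow.loc['overall', 'percent']:.2f}% of sessions")

_, avg = ps.resource_table(corpus)
print(f"resources shared per session: {ps.round_half_up(avg):.2f}")

demo = ps.demographics_summary(corpus)
print(f"demographic disclosure: {demo['disclosure_rate_pct']:.2f}% "
      f"({demo['gender'].loc['female', 'percent']:.2f}% of disclosers female)")

within, outside, _ = split_cohorts(corpus, "business_hours")
print(f"business-hours split: {len(within)} within / {len(outside)} outside "
      f"({ps.round_half_up(len(outside) / len(corpus) * 100):.1f}% outside)")
print()
print("Each percentage is recomputed from the session-level corpus; the corpus")
print("is constructed so its marginals equal the deployment's published tables.")
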