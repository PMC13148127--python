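"""Compare engagement and baseline sentiment between time-of-use cohorts.

Generates a corpus under the default study conditions (engagement and
baselines differ by cohort by design), splits it at the business-hours
boundary (Mon-Fri 08:00-17:00 local, by session start), and prints the
engagement metric table and the stress baseline comparison.
"""

import peersent as ps
from peersent.sessions import split_cohorts

sessions = ps.generate_sessions(ps.default_config(n_sessions=4000, seed=5))
within, outside, _ = split_cohorts(sessions, "business_hours")
print(f"cohorts: {len(within)} within business hours, {len(outside)} outside\n")

table = ps.engagement_summary(sessions).set_index("metric")
for metric, row in table.iterrows():
    stars = ps.significance_marker(row["p_value"])
    print(
        f"{metric:>13}: within {row['mean_within']:8.2f}  outside {row['mean_outside']:8.2f}"
        f"  -> {row['larger_cohort']} larger by {row['percent_difference']:.1f}%{stars}"
    )

comp = ps.compare_baselines(within, outside, "stress")
print(
    f"\nbaseline stress: within {comp.mean_a:.2f} vs outside {comp.mean_b:.2f} "
    f"(Welch p={comp.p_value:.3g}, d={comp.cohens_d:.3f})"
)
print()
print("Outside-hours users stay longer and cover more topics; within-hours users")
print("type faster — the generator encodes these cohort differences and the")
print("comparison table recovers them. The initial-state means sit above the")
print("latent cohort baselines (6.96 vs 6.85) because the initial state is the")
print("maximum of the first three noisy scores, which also shrinks the small")
print("cohort gap; recovery of the latent baselines is checked on the")
print("generator's truth ledger instead.")
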