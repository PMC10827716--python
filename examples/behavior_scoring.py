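"""Behavioral scoring: mNSS totals and a pasta-handling session.

Scores a generated item set on the 0-18 neurological deficit scale and
applies the trial-validity and stop rules to a generated pasta session.
"""

from strokequant import (generate_mnss_items, generate_pasta_log,
                         mnss_relative_change, mnss_total, pasta_summary,
                         select_trials)
from strokequant.behavior import atypical_count

items = generate_mnss_items("47.8", "post_stroke", seed=3)
post_stroke = mnss_total(items)
post_tdcs = mnss_total(generate_mnss_items("47.8", "post_tdcs", seed=4))
print(f"post-stroke mNSS: {post_stroke} / 18 "
      f"(beam {items.beam_balance:.2f}, walking {items.walking})")
print(f"post-stimulation mNSS: {post_tdcs} / 18")
print(f"relative change: {mnss_relative_change(post_stroke, post_tdcs):+.2f} "
      "(positive = improvement)")

session = generate_pasta_log("47.8", "day2", seed=11)
valid = select_trials(session)
print(f"\npasta session: {len(session)} pieces presented, "
      f"{len(valid)} valid (stop after 4 valid or 5 presented)")
for i, t in enumerate(session):
    extra = (f"{t.duration_s:5.1f} s, grasps ipsi/contra "
             f"{t.grasps_ipsi}/{t.grasps_contra}, "
             f"atypicals {atypical_count(t)}" if t.status == "valid"
             else "invalid")
    print(f"  piece {i+1}: {t.status:<14} {extra}")
m = pasta_summary(valid)
print(f"session means: {m.time_per_pasta_s:.1f} s/pasta, "
      f"{m.atypicals_per_pasta:.2f} atypical behaviors/pasta")
print("-> impaired animals eat slowly, shift grasps to the unaffected "
      "limb and show frequent atypical handling")
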