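"""Date a pregnancy from claims: onset from GA annotations, delivery from
entries, trimester windows from the episode."""
import datetime as dt

from kampopreg import (
    GADiagnosis,
    assign_trimester,
    build_episode,
    estimate_delivery,
    estimate_onset,
)

# two prenatal visits with GA annotations; the most recent one dates the
# pregnancy (late-pregnancy dating is the most accurate)
visits = [
    GADiagnosis(dt.date(2015, 1, 5), ga_weeks=8),
    GADiagnosis(dt.date(2015, 6, 1), ga_weeks=38),
]
onset = estimate_onset(visits)
print(f"estimated onset: {onset}  (2015-06-01 minus 38 weeks)")

# a delivery-specific procedure entry wins over the month-midpoint fallback
delivery = estimate_delivery([(dt.date(2015, 6, 3), "specific_procedure")], "2015-06")
print(f"estimated delivery: {delivery.delivery_date} via {delivery.method.value}")

episode = build_episode(onset, delivery)
print(f"gestation: {episode.gestation_days} days, capped: {episode.capped_294}")
print(f"trimester 1: {episode.t1}")
print(f"trimester 2: {episode.t2}")
print(f"trimester 3: {episode.t3}")

probe = onset + dt.timedelta(days=98)
print(f"{probe} is in trimester: {assign_trimester(probe, episode).value}")
# Day 98 is the first day of the second trimester (week 14, day 0).
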