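"""Classify prescriptions into exposure intervals and comparison groups.

The exposure date falls back dispensing -> admission -> 15th of the claim
month; the interval runs for the days of supply; senna glycosides in the
first trimester exclude a mother, and any rhubarb-rhizome Kampo (KRR)
exposure beats MgO for group assignment.
"""
import datetime as dt

from kampopreg import (
    GADiagnosis,
    assign_group,
    build_episode,
    build_intervals,
    default_drug_dictionary,
    estimate_delivery,
    estimate_onset,
    flag_trimester_exposure,
)

dictionary = default_drug_dictionary()
onset = estimate_onset([GADiagnosis(dt.date(2015, 6, 1), 38)])
episode = build_episode(
    onset, estimate_delivery([(dt.date(2015, 6, 3), "specific_procedure")], "2015-06")
)

prescriptions = [
    # MgO with a dispensing date, 14 days of supply, early pregnancy
    dict(drug_code="A02AA02", dispense_date=onset + dt.timedelta(days=20),
         admission_date=None, claim_year_month="2014-09", days_of_supply=14,
         as_needed=False),
    # a rhubarb-rhizome formulation, date resolved from the claim month
    dict(drug_code="mashiningan", dispense_date=None, admission_date=None,
         claim_year_month="2014-10", days_of_supply=7, as_needed=True),
]
intervals = build_intervals(prescriptions, dictionary)
for iv in intervals:
    print(f"{iv.product:12s} {iv.drug_class:4s} {iv.start_date} .. {iv.end_date} "
          f"({iv.date_provenance.value})")

flags = flag_trimester_exposure(intervals, episode)
t1 = {cls: per["t1"] for cls, per in flags.items()}
print(f"first-trimester flags: {t1}")
print(f"group: {assign_group(t1).value}")
# MgO + KRR both in trimester 1 -> the KRR group (group 2), since KRR is
# the exposure of interest and co-prescription does not cancel it.
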