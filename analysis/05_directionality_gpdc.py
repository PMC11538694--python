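"""Directed coupling: who leads?  GPDC on the paired power envelopes.

Fits a bivariate MVAR to each interaction session's (human, dog) frontal
and parietal envelopes and summarizes band-mean GPDC in both directions.
The generator's ground truth has the human leading by 1 s, so
human->dog GPDC should dominate and grow along the day schedule.
"""

import pandas as pd

from _common import RESULTS, demo_study
from dyadscan.directionality import dyad_gpdc
from dyadscan.spectral import session_region_series

rows = []
for session, truth in demo_study():
    if session.meta["condition"] != "interaction":
        continue
    ser = session_region_series(session)
    for region in ("frontal", "parietal"):
        g = dyad_gpdc(ser["human"][region], ser["dog"][region], pmax=8, min_windows=60)
        rows.append(
            {
                **{k: session.meta[k] for k in ("dyad", "day")},
                "region": region,
                "gpdc_human_to_dog": g.human_to_dog,
                "gpdc_dog_to_human": g.dog_to_human,
                "order": g.order,
                "true_leader": truth.leader,
            }
        )
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "gpdc_table.csv", index=False)

print("Band-mean GPDC (0.01-0.4 cycles/s of envelope fluctuation), frontal region:")
print(
    df.query("region == 'frontal'")
    .groupby("day")[["gpdc_human_to_dog", "gpdc_dog_to_human"]]
    .mean()
    .round(3)
    .to_string()
)
share = (df.gpdc_human_to_dog > df.gpdc_dog_to_human).mean()
late = df.query("day >= 4")
share_late = (late.gpdc_human_to_dog > late.gpdc_dog_to_human).mean()
print(f"\nhuman->dog exceeds dog->human in {100 * share:.0f}% of all session-regions, "
      f"{100 * share_late:.0f}% on days 4-5 where the schedule has turned coupling on "
      "(ground-truth leader: human). Table -> results/gpdc_table.csv")
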