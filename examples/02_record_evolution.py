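"""Span-wise record evolution: how much did each event improve?

Pairs each year of 1992-2005 with the corresponding year of 2005-2018,
computes the signed percent change of every event's annual best (positive
= improvement), and ranks events by their mean change.
"""

from recordevo import (
    compare_spans,
    default_panel_spec,
    load_default_catalog,
    rank_events,
    simulate_panel,
)

catalog = load_default_catalog()
panel = simulate_panel(default_panel_spec(seed=1))

evolution = compare_spans(panel, (1992, 2005), (2005, 2018))
ranking = rank_events(evolution, catalog)

print("top and bottom events by mean paired-year improvement (%):")
print(ranking.head(5).to_string(float_format="%.2f"))
print("...")
print(ranking.tail(3).to_string(float_format="%.2f"))
print(f"\nmarathon rank: {int(ranking.loc['marathon', 'rank'])} of {len(ranking)}")
# Positive mean_change = the event's marks got better between the spans;
# negative = "negative growth" (records stagnated or worsened).
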