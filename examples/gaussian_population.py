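"""Analytic predictions for a homogeneous (bell-shaped) population.

Both emotional parameters follow N(1/2, 1/6): 99.73% of draws land in
[0, 1], so the untruncated normal cdf is used directly in the offer
transform.  This population concentrates offers near a quarter of the
pot, qualitatively matching the central tendency seen in laboratory
Ultimatum Game play (though experimental offers centre higher, at
40-50%).
"""

from emoug import make_joint, optimal_offer, summary_table

joint = make_joint("normal", mu=0.5, sigma=1.0 / 6.0)

table = summary_table(joint)
print("Population summary (percent of the pot):")
print(table.to_markdown())

print(
    f"\nRaw (unrounded) median {table.median_offer:.2f}%, "
    f"mean {table.mean_offer:.2f}%, mode {table.modal_offer:.2f}%"
)
print(f"Optimal proposer offer s* = {optimal_offer(joint):.4f}")
print(
    "\nOffers pile up near 24% of the pot and low-ball offers almost"
    "\nvanish (only 4% of offers are at or below 10%), but the model"
    "\nstill rejects 70% of offers in the 1-20% band — the acceptance"
    "\ncurve rises steeply only after 20%.  Note the modal offer lands"
    "\non the 24/25 rounding boundary, and the computed payoff-maximising"
    "\noffer is ~37%, above the population's central offers."
)
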