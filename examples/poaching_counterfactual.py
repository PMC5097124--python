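"""Visits lost to poaching: predicted visits with and without the annual
poaching-driven density decline at each elephant-holding PA.

Prints the regional totals; losses concentrate in savannah regions because
the density effect is strongly reduced in forests.
"""

from elevisits import (SyntheticParams, aggregate_visit_losses,
                       counterfactual_all, fit_visitation_model,
                       generate_pa_table, test_scale_config)

records, _ = generate_pa_table(SyntheticParams(seed=1))
fit = fit_visitation_model(records, test_scale_config(seed=1))
results = counterfactual_all(fit, records)

table = aggregate_visit_losses(results)
print(table.round(1).to_string(index=False))
total = table.loc[table["region"] == "all", "visit_loss"].iloc[0]
print(f"\nAcross all {len(results)} elephant-holding PAs, current poaching "
      f"rates cost about {total:,.0f} tourist visits per year.")
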