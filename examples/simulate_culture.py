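"""Simulate the reference shake-flask batch culture and print its course.

Builds the bundled CHO network, integrates the 46-state mass balances over
six days with regulation terms I+II active, and prints the main culture
variables at the daily sampling times.  Expect cell density to plateau
around day 4 when glutamine is depleted, glucose to stay above 5 mM, and
the ATP/ADP and NADH/NAD ratios to hold near 10 and 0.05 during growth.
"""

import chokinet as ck

net = ck.build_canonical_network()
params = ck.make_clone(ck.CLONES["parental"],
                       ck.ParameterSet.canonical_defaults())
schedule = ck.CultureSchedule()
traj = ck.simulate_batch(net, params, schedule)

print(f"{'t (h)':>6} {'Xv':>6} {'GLC':>6} {'GLN':>6} {'LAC':>6} "
      f"{'ALA':>6} {'ATP/ADP':>8} {'NADH/NAD':>9} {'qO2':>9}")
for t in schedule.sample_times:
    row = [traj.value(v, [t])[0]
           for v in ("Xv", "GLC", "GLN", "LAC", "ALA",
                     "ATP_ADP_ratio", "NADH_NAD_ratio", "qO2")]
    print(f"{t:>6.0f} {row[0]:>6.2f} {row[1]:>6.1f} {row[2]:>6.2f} "
          f"{row[3]:>6.1f} {row[4]:>6.2f} {row[5]:>8.2f} {row[6]:>9.4f} "
          f"{row[7]:>9.2e}")

q = ck.specific_rates(traj)
print("\nSpecific rates at 48 h (mmol/(1e6 cells)/h; mu in 1/h):")
print(q.loc[48.0].to_string(float_format=lambda x: f"{x:.3e}"))
print("\nXv in 1e6 cells/mL; metabolites in mM. Growth stops when "
      "glutamine runs out, while glucose stays in excess.")
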