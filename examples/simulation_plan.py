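"""Simulation-plan accounting for the full study protocol.

Tallies the three simulation campaigns over the eight-receptor panel:
mixed-solvent runs (booked at their cumulative 1.2 μs per receptor),
triplicate 40 ns pure-water runs, and the restrained hydration-site runs
(2 ns equilibration + 20 ns production per site).
"""

from allosite.synthetic import (
    cosolvent_plan, full_study_plan, hydration_site_plan, plan_total_time,
    pure_water_plan,
)

for name, plan in [("cosolvent", cosolvent_plan()),
                   ("pure water", pure_water_plan()),
                   ("hydration sites", hydration_site_plan())]:
    print(f"{name:16s} {plan_total_time(plan):8.0f} ns "
          f"({len(plan.entries)} plan entries)")

total = plan_total_time(full_study_plan())
print(f"{'total':16s} {total:8.0f} ns  = {total / 1000:.2f} us")
# The hydration protocol alone is 8 receptors x 2 sites x 22 ns = 352 ns;
# the whole campaign exceeds 10 microseconds of simulation time.
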