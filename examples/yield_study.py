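"""Active-electrode yield over an 8-week, 4-arm implant study.

Generates a study table (one record per arm/animal/channel/week), excludes
channels that malfunctioned from the outset or were never active, pools
weeks 1-4 and 5-8, and reports each arm's active proportion, its percent
decline between phases, and the pooled two-proportion z-test.
"""

from imequant.synth.study import StudyConfig, gen_study
from imequant import yield_stats as ys

table, truth = gen_study(StudyConfig(seed=1))
viable = ys.viable_channels(table)
p1 = {r.arm: r for r in ys.phase_proportion(table, [1, 2, 3, 4], viable)}
p2 = {r.arm: r for r in ys.phase_proportion(table, [5, 6, 7, 8], viable)}

print(f"{'arm':>10} {'viable':>7} {'W1-4':>7} {'W5-8':>7} {'decline':>8} {'z':>6} {'p':>9}")
for arm in p1:
    a, b = p1[arm], p2[arm]
    z = ys.two_prop_ztest(a.n_active, a.n_viable, b.n_active, b.n_viable)
    decline = ys.phase_decline(a.aey, b.aey)
    print(f"{arm:>10} {a.n_viable // 4:>7} {a.aey:>7.3f} {b.aey:>7.3f} "
          f"{decline:>7.1f}% {z.z:>6.2f} {z.p:>9.2e}")

print("\nEvery arm loses yield late in the study; in expectation the treated")
print("arm declines least (17%) and the free-drug arm most (54%) — a single")
print("7-8 animal study fluctuates around those means by several points.")
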