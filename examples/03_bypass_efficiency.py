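"""Bypass efficiency and fold change between two enzymes.

Simulates damaged (thymine glycol) and undamaged lane sets for a
wild-type-like and a mutant-like enzyme profile, aggregates the bypass
probabilities at the lesion, and reports each enzyme's bypass efficiency
(damaged/undamaged, percent) with the mutant's fold reduction. The
WT-like profile is built to give an efficiency near 18%; the mutant-like
one near 4%, about a five-fold reduction.
"""

import tlsquant as tq

subs = tq.standard_substrates()
dam_sub, und_sub = subs["14/Tg"], subs["14/T"]
profiles = tq.example_profiles(dam_sub.k, dam_sub.lesion_n)

summaries = {}
for i, label in enumerate(("WT-like", "mutant-like")):
    arms = {}
    for j, (arm, sub) in enumerate((("damaged", dam_sub), ("undamaged", und_sub))):
        cond = tq.ReactionConditions(
            seed=100 + 10 * i + j, times=(2.0, 4.0, 6.0), replicates=2,
            molecules=50_000, engagement_rate=0.05, noise_sigma_mult=0.05,
        )
        lanes = tq.simulate_lanes(profiles[label][arm], sub, cond)
        arms[arm] = tq.aggregate(lanes, dam_sub.lesion_n)
    summaries[label] = tq.efficiency_from_summaries(arms["damaged"],
                                                    arms["undamaged"])
    s = summaries[label]
    print(f"{label:<12} bypass {tq.format_percent(100 * s.bypass_mean)}% "
          f"(undamaged {tq.format_percent(100 * arms['undamaged'].bypass_mean)}%) "
          f"-> efficiency {tq.format_percent(s.efficiency_pct)}%"
          f" +/- {tq.format_percent(s.efficiency_sd_pct)}")

fc = tq.fold_change(summaries["WT-like"], summaries["mutant-like"])
print(f"\nmutant-like reduces bypass efficiency {fc.ratio:.1f}-fold "
      f"(nearest integer: {fc.fold})")
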