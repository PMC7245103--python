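"""Seeding and the embedded autocatalytic loop.

Part 1 seeds the standard growth run with preformed {Mo36} template and
shows the induction period collapse while the initial rate saturates.
Part 2 re-runs the {Mo36} subsystem with and without template rules: with
the embedded autocatalysis removed, the {Mo36} abundance collapses.
"""

from moblue import experiments

print("-- seeding with preformed {Mo36} --")
df = experiments.seeding_curve(seed_amounts=(0, 1, 4, 16), n_reps=12, seed=0)
print(df.to_string(index=False))
# lag drops to ~0 as soon as any template is present (the autocatalytic
# cycle no longer has to wait for the first spontaneous {Mo36}), and the
# initial rate stops growing once the template machinery is saturated.

print("\n-- template ablation on the {Mo36} subsystem --")
res = experiments.ablation_experiment(n_reps=30, seed=0)
print(f"time-averaged Mo36, templated: {res['templated']:.2f}")
print(f"time-averaged Mo36, ablated:   {res['ablated']:.3f}")
print(f"fold change: {res['fold_change']:.1f}x")
# Without the loop in which a completed {Mo36} accelerates the condensation
# of its own fragments, the uncatalyzed pathway alone leaves the template
# more than tenfold less abundant.
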