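"""Train the FLDA decoder and decode one simulated oddball trial.

Builds a training set (one 10-repetition trial per interface item), fits
the Fisher discriminant on the 100-dimensional flash features, then decodes
a fresh 5-repetition trial in which the simulated subject attends item 6
("Move to the left 20 cm" / sub-goal 6).
"""

from cvta import erp, simulate

# offline training: 12 trials x 10 repetitions = 840 flash epochs
trials = []
for item in range(1, 13):
    sched = erp.build_schedule(10, seed=100 + item)
    rec = simulate.generate_erp_recording(
        simulate.ErpSimConfig(seed=item), sched, item
    )
    trials.append((rec, sched, item))
model = erp.train_decoder(trials)
print(f"trained FLDA: {model.w.size} weights, w0 = {model.w0:.3f}")

# online trial: 5 repetitions, attended item 6
target = 6
sched = erp.build_schedule(5, seed=77)
rec = simulate.generate_erp_recording(simulate.ErpSimConfig(seed=78), sched, target)
decoded = erp.classify_target(rec, sched, model)
print(f"attended item {target}, decoded item {decoded}")
print(f"  single-step command: {erp.SS_LABELS[erp.item_to_command(decoded, 'SS')]}")
print(f"  sub-goal command:    {erp.item_to_command(decoded, 'CVT')}")
# Decoding sums discriminant scores per row and column group over all
# repetitions; the attended item sits at the intersection of the winning
# row and column.
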