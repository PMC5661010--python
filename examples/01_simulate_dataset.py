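"""Generate a synthetic amyloid-challenge study dataset.

Emulates the full design: 10 conditions (control + 3 proteins x 3
aggregation states), 3 biological x 2 technical replicates, 232 buckets over
78 metabolites with 8 planted key metabolites and per-sample dilution.
"""

from nmrfingerprint import SyntheticConfig, generate_bucket_table

table, metadata, truth = generate_bucket_table(SyntheticConfig(seed=1))

print(f"samples:            {table.n_samples}")
print(f"buckets:            {table.n_buckets}")
print(f"annotated buckets:  {sum(1 for b in table.buckets if b.annotation)}")
print(f"metabolites:        {len(table.annotation_map())}")
print(f"key metabolites:    {', '.join(truth.key_metabolites)}")
print(f"conditions:         {len({m.condition for m in metadata})}")

# The key metabolites carry condition-specific fold changes (1.5-3x, random
# direction); everything else varies only by replicate noise and dilution.
fc = truth.fold_changes[truth.key_metabolites[0]]
print(f"\nfold changes planted on {truth.key_metabolites[0]} per condition:")
for cond, v in fc.items():
    print(f"  {cond:<18s} {v:.2f}")
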