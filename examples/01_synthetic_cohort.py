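"""Generate a paired plaque/abscess cohort with known ground truth.

Prints the cohort dimensions, the filtering log, and the planted
differential-abundance truth that later stages are expected to recover.
"""

import oralpair as op

cfg = op.GeneratorConfig(seed=42)
ct, md, tax, truth = op.generate_cohort(cfg)
print(f"raw cohort: {len(ct.taxa)} taxa x {len(ct.samples)} samples "
      f"({len(md.pairs())} patient pairs, {len(md.blanks())} blanks)")

ct, md, log = op.filter_cohort(ct, md, contaminants=truth.contaminant_taxa)
print(f"after filtering: {len(ct.taxa)} taxa x {len(ct.samples)} samples; "
      f"{len(log)} removals logged")

by_dir = {}
for taxon, direction in truth.enriched_taxa.items():
    by_dir.setdefault(direction, []).append(taxon)
print(f"planted truth: {len(by_dir.get('plaque', []))} plaque-enriched and "
      f"{len(by_dir.get('abscess', []))} abscess-enriched taxa")
print("topic classes:", truth.topic_class)
# Each sample is a multinomial draw from a mixture of these topics; a high
# type_bias concentrates each specimen type on its own topics, which is what
# makes the enriched taxa detectable downstream.
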