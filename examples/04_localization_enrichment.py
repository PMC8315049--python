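"""Bootstrap test of subcellular-localization enrichment.

For each response group, the proportion of intracellular/extracellular
proteins is compared against resamples (with replacement) of the
differential-protein background; the add-one p-value has resolution
1/(n_boot + 1), so 10,000 repeats can report p < 0.0001 but never 0.
"""

import cartisec as cs
from cartisec.grouping import GROUPS, classify_all
from cartisec.preprocess import (
    filter_all_replicates,
    filter_min_fraction,
    impute_half_min,
    presence_mask,
    sum_over_timepoints,
)

table, truth, annotation = cs.simulate_dataset(cs.GeneratorConfig(seed=1))
filtered = filter_min_fraction(filter_all_replicates(table))
mask = presence_mask(filtered)
summed = sum_over_timepoints(impute_half_min(filtered))
records = cs.run_contrasts(summed, list(cs.CANONICAL_CONTRASTS))
assignments = classify_all(records, mask)

grouped = [a for a in assignments if a.group in GROUPS]
background = [a.protein_id for a in grouped]
for g in GROUPS:
    members = [a.protein_id for a in grouped if a.group == g]
    for category in ("intracellular", "extracellular"):
        res = cs.bootstrap_proportion_test(
            members, background, annotation, category, n_boot=10_000, seed=1,
            group_label=g,
        )
        print(
            f"group {g:>3} {category:<13} observed {res.observed_prop:.2f} "
            f"background {res.background_prop:.2f} p={res.p_boot:.4g} ({res.tail})"
        )

# Group II (planted 4% extracellular) shows strong intracellular
# enrichment; Groups I and III lean extracellular - the localization
# structure the generator plants to mirror the secretome biology.
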