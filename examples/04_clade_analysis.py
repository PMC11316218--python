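"""Interpret a rooted tree: monophyly, clade assignment, concordance.

Runs the tree stage on a synthetic dataset that includes the reference
sequences as leaves, then asks the questions the survey asks of its tree:
are the ASCL and ORS references monophyletic, where does each query fall,
and does tree placement agree with the residue-based label?
"""

from pks3.classify import classify_all
from pks3.clades import concordance_report, count_maximal_clades, is_monophyletic
from pks3.msa import progressive_align
from pks3.phylo import bootstrap_support, root_with_outgroup
from pks3.simulate import SyntheticFamilySpec, generate_dataset

spec = SyntheticFamilySpec(
    seed=5,
    n_per_class={"ASCL": 2, "ORS": 3, "other_PKSIII": 2, "not_PKSIII": 0},
    fusion_fraction=0.0,
)
dataset = generate_dataset(spec)
profiles = [dataset.profiles[c] for c in ("ASCL", "ORS", "other_PKSIII")]
reference_labels = {p.name: p.class_tag for p in profiles}

records = dataset.records + [p.record for p in profiles]
msa = progressive_align(records)
tree = root_with_outgroup(bootstrap_support(msa, n_reps=50, seed=5), "outgroup")

results = classify_all(dataset.records, profiles)
report = concordance_report(results, tree, reference_labels)

print("monophyly:", report.monophyly)
print("concordance: %.0f%%" % report.percent_concordant)
for qid, clade in sorted(report.clade_assignments.items()):
    print(f"  {qid:<18} residue={report.residue_labels[qid]:<13} clade={clade}")

lineages = {rec.id: dataset.taxa[rec.id].lineage_group for rec in records if rec.id in dataset.taxa}
lineages.update({p.name: "reference" for p in profiles})
n_bryo = count_maximal_clades(tree, lambda g: g == "bryophyte", lineages)
print("maximal all-bryophyte clades:", n_bryo)
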