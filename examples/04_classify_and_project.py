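"""Train, cross-validate, and apply a classifier on extracted features.

Builds on the supervised pipeline: breadth features -> Random Forest
(fit + stratified CV), predictions for held-out samples recomputed from
the stored contigs FASTA alone, and a PCA projection of all samples.

Run:  python examples/04_classify_and_project.py
"""

from pathlib import Path

import dbgfeat as d

base = Path("example_output/04")
base.mkdir(parents=True, exist_ok=True)

community = d.generate_community(d.CommunitySpec(seed=42), base / "community")
run_dir = base / "run"
d.run_supervised(
    d.PipelineConfig(
        mode="unique",
        out_dir=run_dir,
        reads_dir=community.reads_dir,
        metadata=community.metadata_path,
        seed=42,
    )
)
table = d.FeatureTable.read_tsv(run_dir / "features_breadth.tsv")
labels = d.GroupLabels(dict(community.assignment))

# cross-validation (10-fold; stratification falls back to plain K-fold
# when folds exceed the smallest class size)
cv = d.cross_validate(table, labels, folds=10, seed=42)
print(f"10-fold CV: accuracy {cv['mean']['accuracy']:.3f}, "
      f"macro-F1 {cv['mean']['f1_macro']:.3f}, MCC {cv['mean']['mcc']:.3f}")

# fit on everything, persist, reload
model = d.fit(table, labels, seed=42, k=community.spec.k)
model.save(base / "model.joblib")
model = d.TrainedModel.load(base / "model.joblib")

# score "new" samples straight from their read files via the stored contigs:
# calc_features re-k-merizes the contigs, so training features reproduce
# bit-exactly and novel samples are directly comparable
new_table = d.calc_features(
    run_dir / "components.fasta",
    dict(community.sample_fastas),
    k=community.spec.k,
    feature_order=model.feature_ids,
)
preds = d.predict(model, new_table)
correct = sum(preds[s][0] == community.assignment[s] for s in preds)
print(f"predictions: {correct}/{len(preds)} correct")
for sid in sorted(preds)[:3]:
    label, probs = preds[sid]
    print(f"  {sid}: {label} {probs}")

# unsupervised view: PCA of the breadth features
proj = d.pca(table, n_components=2)
print(f"\nPCA explained variance ratio: {proj.explained_variance_ratio.round(3)}")
print(proj.coordinates.round(3))
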