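"""Statistical k-mer selection: chi-squared and the chi-squared+Mann-Whitney
conjunction.

Strict Bonferroni correction over every tested k-mer sets a hard floor on
the sample count: with 6-vs-6 samples the best achievable Yates p-value is
3.9e-3, which can never survive correction over thousands of k-mers.  This
example therefore simulates 16 samples per group (small genomes keep it
fast) and shows both selection modes finding the planted markers.

Run:  python examples/02_statistical_selection.py
"""

from pathlib import Path

import dbgfeat as d

base = Path("example_output/02")
base.mkdir(parents=True, exist_ok=True)

spec = d.CommunitySpec(
    n_background_genomes=2,
    genome_length=1200,
    samples_per_group=16,
    markers_per_group=1,
    marker_length=450,
    coverage=8.0,
    seed=19,
)
community = d.generate_community(spec, base / "community")
tables = {
    sid: d.count_sample_file(path, k=spec.k, min_count=2)
    for sid, path in community.sample_fastas.items()
}
labels = d.GroupLabels(dict(community.assignment))

# chi-squared presence test (Yates continuity + Bonferroni)
presence = d.build_presence_matrix(tables, labels)
print(f"tested k-mers: {len(presence)}")
for cat in labels.categories:
    sel = d.select_chisq(presence, cat, alpha=0.05)
    print(
        f"chisq  {cat}: {len(sel):5d} selected; "
        f"best statistic {sel.statistic[0]:.2f}, "
        f"corrected p {sel.p_corrected[0]:.2e}"
    )

# conjunction: chi-squared presence AND Mann-Whitney abundance shift
for cat in labels.categories:
    sel = d.select_stats(tables, labels, cat, alpha=0.05)
    print(f"stats  {cat}: {len(sel):5d} selected (presence AND abundance tests)")

# a single k-mer's contingency, for intuition
sel = d.select_chisq(presence, labels.categories[0], alpha=0.05)
scores = sel.scores
km = max(scores, key=scores.get)
print(f"\nexample selected k-mer {km}: per-group sample counts {presence.counts_for(km)}")
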