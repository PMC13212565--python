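"""Group comparison with the normality gate and compact letter display.

Contrasts genic GC across the four simulated lineages. The scaffold picks
ANOVA + pairwise Welch t or Kruskal-Wallis + pairwise Wilcoxon from a
Shapiro-Wilk gate on pooled residuals, Holm-adjusts the pairwise family
and renders letters: lineages sharing a letter are not significantly
different at alpha = 0.05.
"""

from limnoscope import synthetic
from limnoscope.genome_metrics import metrics_table
from limnoscope.stats import compare_groups

config = synthetic.study_config(seed=1, n_genomes=8, genes_reference=80)
bundle = synthetic.simulate(config)
table = metrics_table(bundle.genomes)

groups = {
    name: table.loc[table["lineage"] == name, "gc_genic_pct"].to_numpy()
    for name in [spec.name for spec in config.lineages]
}
report = compare_groups(groups)
print(f"test used: {report.test_used}")
print(f"global p:  {report.global_p:.3e}")
for name in report.groups:
    print(f"  {name:<20s} median GC {sorted(groups[name])[len(groups[name])//2]:6.2f}"
          f"  letters: {report.letters[name]}")
print(
    "\nDistinct letters separate the GC-eroded lineage from the three "
    "high-GC lineages; shared letters mark statistically indistinguishable "
    "groups."
)
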