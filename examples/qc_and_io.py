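"""Quality control and marker intersection on genotype data.

Writes a simulated panel to phased VCF, reads it back, then runs the QC
filters (call rate > 95%, exact Hardy-Weinberg P > 0.05) and intersects
marker maps across two panels.
"""

import tempfile
from pathlib import Path

import numpy as np

import popdiff as pp

cfg = pp.SyntheticConfig(n_pops=2, n_samples_per_pop=100, n_snps=200, seed=11)
panel = pp.balding_nichols_panel(cfg).panel

with tempfile.TemporaryDirectory() as tmp:
    vcf, labels = Path(tmp) / "panel.vcf", Path(tmp) / "labels.tsv"
    pp.write_haplotype_panel(panel, vcf, labels)
    panel = pp.read_haplotype_panel(vcf, labels)
print(f"round-tripped phased VCF: {panel.n_samples} samples x "
      f"{panel.n_markers} markers")

g = panel.to_genotypes()
# knock out some genotypes so the call-rate filter has something to do
rng = np.random.default_rng(0)
vals = g.values.copy()
vals[rng.random(vals.shape) < 0.002] = pp.MISSING
vals[:, 0] = pp.MISSING  # one dead marker
g = pp.GenotypeMatrix(vals, g.sample_ids, g.populations, g.snp_map)

g_cr = pp.call_rate_filter(g, min_rate=0.95)
g_qc = pp.hwe_filter(g_cr, alpha=0.05)
print(f"call-rate filter: {g.n_markers} -> {g_cr.n_markers} markers")
print(f"HWE filter (exact test per population): -> {g_qc.n_markers} markers")

sub = panel.subset_markers(np.arange(50, panel.n_markers))
common = pp.intersect_markers([panel, sub])
print(f"marker intersection of two panels: {common[0].n_markers} shared SNPs")
print("# A/T and C/G SNPs would be dropped here as strand-ambiguous.")
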