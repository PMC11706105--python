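"""Generate a synthetic case/control study with known ground truth.

Simulates an RNA-seq cohort (negative-binomial counts with planted
differential expression), a small proteome (log-normal intensities with
some proteins detected in only one group), and writes them to TSV.
"""

from pathlib import Path

from revscreen import io as rio
from revscreen.simulate import simulate_cohort_counts, simulate_proteome_intensities

out = Path("scratch/example_study")
out.mkdir(parents=True, exist_ok=True)

counts, t_truth = simulate_cohort_counts(
    n_case=20, n_control=20, n_genes=2000, de_fraction=0.1, seed=0
)
prots, p_truth = simulate_proteome_intensities(
    n_case=3, n_control=3, n_proteins=500, de_fraction=0.1,
    onegroup_fraction=0.2, seed=1
)

rio.write_matrix(counts, out / "counts.tsv", out / "counts_metadata.tsv")
rio.write_matrix(prots, out / "intensities.tsv", out / "intensities_metadata.tsv")
rio.write_truth(t_truth, out / "truth_transcripts.json")
rio.write_truth(p_truth, out / "truth_proteins.json")

print(f"cohort: {len(counts.gene_ids)} genes x {len(counts.sample_ids)} samples, "
      f"{len(t_truth.de_genes)} genes with planted effects")
print(f"proteome: {len(prots.gene_ids)} proteins x {len(prots.sample_ids)} samples, "
      f"{len(p_truth.one_group_proteins)} detected in only one group")
print(f"written to {out}/")
# The planted truth files record which genes carry real effects, so any
# downstream differential-expression call can be checked against them.
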