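"""Read-level cobamide gene profiling on a simulated multi-study dataset.

Simulates profile-HMM hit tables for a 30-species community across two
studies, runs the filtering/normalization pipeline, and prints per-taxon
contributions and the metagenomic producer calls.
"""

from cobashare import read_profiling as rp
from cobashare import synthetic_data as syn

community = syn.make_community(n_species=30, n_producers=4, n_salvagers=5,
                               frac_dependent=0.4, seed=11)
hits, taxonomy, metadata, truth = syn.simulate_hit_table(
    community, n_samples=12, n_studies=2, reads_per_sample=2000,
    fp_rate=0.0, seed=12)

# E-value cutoff (1e-6) and one best hit per read
best = {s: rp.select_best_hits(v) for s, v in hits.items()}

# coverage-gated (>=20% of HMM length), normalized gene x taxon table
table = rp.build_gene_taxon_table(best, taxonomy, metadata, truth.hmm_lengths)
table = rp.filter_rare_pairs(table, metadata)  # >=5 samples, >=2 studies

sample = sorted(table.samples)[0]
contrib = rp.taxon_contribution(table, sample, set(rp.MARKER_GENES_11))
top = sorted(contrib.items(), key=lambda kv: -kv[1])[:5]
print(f"top biosynthesis-gene contributors in {sample} "
      "(share of length-normalized hits):")
for taxon, share in top:
    print(f"  {taxon}: {share:.3f}")

producers = rp.call_metagenomic_producers(table)
print(f"\nspecies with >=5 of 10 biosynthesis markers detected: "
      f"{len(producers)}")
print(f"planted de novo producers:                             "
      f"{len(truth.producers)}")
print("recovered exactly the planted set:", producers == truth.producers)
# The contribution shares say how much of the sample's cobamide biosynthesis
# signal each species carries; the producer call mirrors a >=5-of-10 marker
# rule applied to read evidence.
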