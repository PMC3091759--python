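"""Library coverage arithmetic and a survey-style report.

Computes genome-equivalent coverage for two BAC libraries (one
restriction-digest, one random-shear), simulates a small library, and
assembles the standard survey report sections.
"""

from beskit import synthetic_data as synth
from beskit.stats_report import (
    build_report, gc_content, genomic_coverage, total_length_stats,
)

# a 23,040-clone BamHI library (80% true clones, 139-kb inserts) and a
# 30,720-clone random-shear library (77% true, 120-kb inserts) on a
# 454-Mb genome
for name, args in [("restriction", (23_040, 0.8, 139, 454)),
                   ("random-shear", (30_720, 0.77, 120, 454))]:
    print(f"{name} library coverage: x{genomic_coverage(*args)} genome equivalents")

genome = synth.simulate_genome(1, 150_000, synth.FeatureRequest(), seed=31)
spec = synth.LibrarySpec(n_clones=500, mean_insert=5_000, insert_sd=300,
                         method=synth.LibrarySpec.Method.RANDOM_SHEAR, seed=32)
pairs = synth.simulate_library(genome, spec)
reads = [p.forward for p in pairs] + [p.reverse for p in pairs]
stats = total_length_stats(reads, genome_size_mb=0.15)

report = build_report(
    config={"seed": 31},
    library_stats={"n_clones": spec.n_clones, "mean_insert": spec.mean_insert},
    sequence_stats={"gc_percent": gc_content([r.record for r in reads]),
                    **stats.__dict__},
)
print(f"{stats.count} reads, mean {stats.mean_bp} bp, total {stats.total_mb} Mb "
      f"({stats.genome_fraction_percent}% of the genome)")
print("report sections:", list(report.sections))
# coverage = true clones x mean insert / genome size; the report bundles
# each stage's summary with the config that produced it.
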