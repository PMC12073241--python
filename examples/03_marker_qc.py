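"""QC of a KASP call matrix: filter cascade, strand fix, complete LD.

Builds the default 38-marker synthetic panel whose contamination profile
mimics a real validation assay (failed assays with massive missing
rates, two grossly heterozygous assays, monomorphic assays, one
ultra-rare allele) and runs the exclusion cascade.
"""

from sproutval import SimulationConfig, simulate_panel
from sproutval import qc_stats, apply_filters, drop_heterozygotes, harmonize_strand, detect_complete_ld
from sproutval.marker_qc import retained_markers

cfg = SimulationConfig(rng_seed=7, exact_counts=True)
matrix, meta, _ = simulate_panel(cfg)

# one assay was designed on the complementary strand; map it back first
matrix, meta = harmonize_strand(matrix, meta)

report = apply_filters(qc_stats(matrix, meta))
print(report["reason"].value_counts().rename("markers").to_string())
kept = retained_markers(report)
print(f"\nretained {len(kept)} of {len(report)} markers")

filtered = drop_heterozygotes(matrix[kept], meta)
for group in detect_complete_ld(filtered):
    print("complete-LD group:", " = ".join(group))
print("\nEach LD group carries one independent signal; downstream model")
print("selection keeps a single representative per group.")
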