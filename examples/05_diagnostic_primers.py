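"""Species-specific diagnostic primer screen.

Fragments a target taxon's coding sequences into 200-bp windows (50-bp
step), discards windows found in any other panel genome, designs primer
pairs (Wallace Tm 53-60 degC, GC 40-60%, 100-200 bp product) on the
surviving regions, and verifies each pair by in-silico PCR against every
genome. UNIQUE = one band in the target, none anywhere else.
"""
from tephrimark.diagnostics import screen_panel
from tephrimark.simulate import SimConfig, make_cds_set, simulate_dataset

cfg = SimConfig(n_taxa=6, n_loci=10, unique_length=1000,
                background_length=30_000, seed=5)
genomes, _, _, truth = simulate_dataset(cfg)
cds_sets = make_cds_set(genomes, truth)

target = genomes[0].taxon
reports = screen_panel(cds_sets, genomes, target)
print(f"target {target}: {len(reports)} verified primer pairs\n")
print("verdict             fwd / rev                     Tm (C)  product")
for r in reports[:5]:
    p = r.primer_pair
    print(f"{r.verdict:18s} {p.fwd}")
    print(f"{'':18s} {p.rev}  {p.tm_fwd:.0f}/{p.tm_rev:.0f} {p.product_size:8d} bp")
amp = reports[0].amplicons
print("\namplicons per genome (first pair):",
      {t: len(v) for t, v in amp.items()})
# exactly one amplicon in the target and zero elsewhere: a single
# diagnostic band on a (virtual) gel.
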