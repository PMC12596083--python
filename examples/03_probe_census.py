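"""Design a 376-bp FISH probe from a CR's LTR and census its copies.

The probe window maximizes (centromeric - non-centromeric) copy count; a
copy is a gapless full-length match at <= 3% mismatches on either strand.
The cumulative length column is copies x 376 bp, as in a FISH probe
census table.
"""

from centrotrace import (SimConfig, call_crs, count_probe_copies,
                         design_probe, generate_genome, probe_report)
from centrotrace.io import is_centromeric

cfg = SimConfig(n_chroms=2, chrom_len=1_500_000, cen_len=300_000,
                planted_cr_copies_cen=12, planted_cr_copies_noncen=2,
                background_copies=10, extra_ltr_solo_copies_cen=6, seed=3)
sim = generate_genome(cfg)
cens = sim.truth.centromeres

cen_elements = [e for e in sim.truth.elements
                if e.family_id == sim.truth.cr_family
                and is_centromeric(e.span, cens)]
cr_ids, rep_id = call_crs(sim.truth.consensi[sim.truth.cr_family],
                          cen_elements, sim.genome)
rep = next(e for e in cen_elements if e.element_id == rep_id)

probe = design_probe(rep, sim.genome, cens, probe_len=376)
print(f"probe source: {probe.source_interval.chrom_id}:"
      f"{probe.source_interval.start}-{probe.source_interval.end} "
      f"(window of the representative's LTR)")

counts = count_probe_copies(probe, sim.genome)
print(probe_report(counts, 376).to_string(index=False))

# Copy numbers reflect the planted CR LTRs (two per full element plus solo
# LTRs); cumulative_len is exactly copies x 376.
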