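"""Domain-architecture feature calls on a hand-made domain table.

Sigma factors need the Sigma70_r2 domain (PF04542) plus a region-4
domain (PF04545 or PF08281); groups follow from the region-1.2/region-3
domains.  Chaplins carry PF03777.  PPTases carry PF01648 at E < 1e-3;
two non-overlapping transferase domains make the call Sfp-type instead
of AcpS-type.
"""

from panstrep import (
    DomainHit,
    classify_sigma,
    classify_tf,
    group_hits_by_protein,
    identify_chaplins,
    identify_pptases,
    load_tf_rules,
)

hits = [
    # housekeeping-like sigma factor: r1_2 + r2 + r3 + r4
    DomainHit("sigA", "PF00140", "Sigma70_r1_2", 1e-30, 10, 90),
    DomainHit("sigA", "PF04542", "Sigma70_r2", 1e-40, 100, 170),
    DomainHit("sigA", "PF04539", "Sigma70_r3", 1e-25, 180, 240),
    DomainHit("sigA", "PF04545", "Sigma70_r4", 1e-30, 250, 310),
    # extracytoplasmic-function sigma factor: r2 + r4_2 only
    DomainHit("sigE", "PF04542", "Sigma70_r2", 1e-20, 5, 70),
    DomainHit("sigE", "PF08281", "Sigma70_r4_2", 1e-18, 90, 150),
    # TetR-family repressor
    DomainHit("tetR1", "PF00440", "TetR_N", 1e-22, 5, 60),
    # chaplin
    DomainHit("chp1", "PF03777", "ChpA-C", 1e-8, 1, 50),
    # Sfp-type PPTase: two separated transferase domains
    DomainHit("pptB", "PF01648", "ACPS", 1e-9, 1, 110),
    DomainHit("pptB", "PF01648", "ACPS", 1e-7, 130, 230),
    # AcpS-type PPTase: a single domain
    DomainHit("pptA", "PF01648", "ACPS", 1e-12, 1, 115),
]
grouped = group_hits_by_protein(hits)

sigma = classify_sigma(grouped)
for pid, call in sigma.items():
    print(f"{pid}: {call.family} {call.group}")

tf = classify_tf(grouped, load_tf_rules(), sigma)
print("transcription factors:", tf)
print("chaplins:", sorted(identify_chaplins(grouped)))
for pid, call in identify_pptases(grouped).items():
    print(f"{pid}: PPTase, {call.pptase_type}-type ({call.n_domains} domain(s))")
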