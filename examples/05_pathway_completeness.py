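"""Beta-ketoadipate pathway completeness for a synthetic cohort.

The protocatechuate and catechol branches each need six reactions, the
last three shared.  A genome is complete for a branch iff it encodes
at least one acceptable KO for every step.  The relaxed KO rule
rescues proteins whose best hit misses the adaptive score threshold
but has independent E < 1e-80.
"""

from panstrep import assign_ko, branch_summary, load_beta_ketoadipate

definitions = load_beta_ketoadipate()
proto, cat = definitions["protocatechuate"], definitions["catechol"]

# raw KO hits: (protein, KO, score, adaptive threshold, independent E)
raw = [
    ("gA_p1", "K00448", 210.0, 150.0, 1e-60),   # passes the standard rule
    ("gA_p2", "K01857", 90.0, 120.0, 1e-95),    # rescued by the relaxed rule
    ("gA_p3", "K01607", 180.0, 150.0, 1e-45),
    ("gA_p4", "K01055", 160.0, 140.0, 1e-50),
    ("gA_p5", "K01031", 200.0, 150.0, 1e-70),
    ("gA_p6", "K00632", 240.0, 180.0, 1e-85),
    ("gB_p1", "K01055", 160.0, 140.0, 1e-50),   # shared steps only
    ("gB_p2", "K01031", 200.0, 150.0, 1e-70),
    ("gB_p3", "K00632", 240.0, 180.0, 1e-85),
]
assignments = assign_ko(raw, relaxed=True)
print(f"KO assignments: {[(a.protein_id, a.ko) for a in assignments]}")

genome_kos = {
    "genomeA": {a.ko for a in assignments if a.protein_id.startswith("gA")},
    "genomeB": {a.ko for a in assignments if a.protein_id.startswith("gB")},
}
summary = branch_summary(genome_kos, proto, cat)
print(summary.to_string())
print("\ngenomeA completes the protocatechuate branch; genomeB has only the")
print("three shared terminal reactions, so both branches are incomplete.")
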