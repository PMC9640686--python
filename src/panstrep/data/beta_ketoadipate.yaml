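# Default beta-ketoadipate pathway definitions.
#
# Two six-step branches funnel aromatic ring-cleavage products into the
# TCA cycle: protocatechuate (pca genes) and catechol (cat genes).  The
# last three reactions -- enol-lactone hydrolase, beta-ketoadipate:
# succinyl-CoA transferase, and beta-ketoadipyl-CoA thiolase -- are
# shared by both branches.  Each step lists the KEGG Orthology terms
# accepted as evidence for that reaction (OR semantics; multi-subunit
# enzymes and isoenzymes each appear as alternative KOs).  The KO sets
# are editable defaults: review them against the current KEGG release
# for your organisms before drawing biological conclusions.
pathways:
  - pathway_id: protocatechuate
    shared_with: catechol
    shared_steps: [4, 5, 6]
    steps:
      - name: protocatechuate_3_4_dioxygenase
        kos: [K00448, K00449]
      - name: 3_carboxy_cis_cis_muconate_cycloisomerase
        kos: [K01857]
      - name: 4_carboxymuconolactone_decarboxylase
        kos: [K01607, K14727]
      - name: beta_ketoadipate_enol_lactone_hydrolase
        kos: [K01055, K14727]
      - name: beta_ketoadipate_succinyl_coa_transferase
        kos: [K01031, K01032]
      - name: beta_ketoadipyl_coa_thiolase
        kos: [K00632, K07823]
  - pathway_id: catechol
    shared_with: protocatechuate
    shared_steps: [4, 5, 6]
    steps:
      - name: catechol_1_2_dioxygenase
        kos: [K03381]
      - name: muconate_cycloisomerase
        kos: [K01856]
      - name: muconolactone_isomerase
        kos: [K03464]
      - name: beta_ketoadipate_enol_lactone_hydrolase
        kos: [K01055, K14727]
      - name: beta_ketoadipate_succinyl_coa_transferase
        kos: [K01031, K01032]
      - name: beta_ketoadipyl_coa_thiolase
        kos: [K00632, K07823]
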