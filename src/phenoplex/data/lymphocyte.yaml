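# Lymphocyte panel: CD20, CD4, CD8, PD1, FOXP3 + DAPI counterstain.
# T-cell phenotype fractions are reported over the CD20-negative parent
# population (large neoplastic CD20+ LP cells fall outside it by construction).
panel:
  name: lymphocyte
  markers:
    - {name: CD20, channel: 0, localization: membranous}
    - {name: CD4, channel: 1, localization: membranous}
    - {name: CD8, channel: 2, localization: membranous}
    - {name: PD1, channel: 3, localization: membranous}
    - {name: FOXP3, channel: 4, localization: nuclear}
    - {name: DAPI, channel: 5, localization: nuclear, counterstain: true}
phenotypes:
  - name: B-cell
    expression: "CD20+"
  - name: CD4+FOXP3+
    expression: "CD20- AND CD4+ AND FOXP3+"
    parent: "CD20-"
  - name: CD4+PD1+
    expression: "CD20- AND CD4+ AND PD1+"
    parent: "CD20-"
  - name: CD8+PD1+
    expression: "CD20- AND CD8+ AND PD1+"
    parent: "CD20-"
  - name: CD4+CD8+PD1+
    expression: "CD20- AND CD4+ AND CD8+ AND PD1+"
    parent: "CD20-"
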