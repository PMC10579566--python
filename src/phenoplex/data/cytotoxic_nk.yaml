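# Cytotoxic / NK-cell panel: CD8, CD16, CD56, NKG2A, GZMB, GNLY + DAPI.
# NK-cell defining rule: CD8- AND [CD16+ AND/OR CD56+] AND
# [NKG2A+ AND/OR GZMB+ AND/OR GNLY+]; CD8+ cells are excluded from the
# NK class by the explicit CD8- term, so NK-cell and CD8+ T-cell labels
# are mutually exclusive. NK subsets are fractions of the NK parent,
# CD8 subsets fractions of the CD8+ parent.
panel:
  name: cytotoxic_nk
  markers:
    - {name: CD8, channel: 0, localization: membranous}
    - {name: CD16, channel: 1, localization: membranous}
    - {name: CD56, channel: 2, localization: membranous}
    - {name: NKG2A, channel: 3, localization: membranous}
    - {name: GZMB, channel: 4, localization: cytoplasmic}
    - {name: GNLY, channel: 5, localization: cytoplasmic}
    - {name: DAPI, channel: 6, localization: nuclear, counterstain: true}
phenotypes:
  - name: NK-cell
    expression: &nk "CD8- AND [CD16+ AND/OR CD56+] AND [NKG2A+ AND/OR GZMB+ AND/OR GNLY+]"
  - name: CD8+ T-cell
    expression: "CD8+"
  - name: CD56+NKG2A+
    expression: "(CD8- AND [CD16+ AND/OR CD56+] AND [NKG2A+ AND/OR GZMB+ AND/OR GNLY+]) AND CD56+ AND NKG2A+"
    parent: *nk
  - name: CD16+GZMB+
    expression: "(CD8- AND [CD16+ AND/OR CD56+] AND [NKG2A+ AND/OR GZMB+ AND/OR GNLY+]) AND CD16+ AND GZMB+"
    parent: *nk
  - name: CD8+NKG2A+
    expression: "CD8+ AND NKG2A+"
    parent: "CD8+"
  - name: CD8+CD16+
    expression: "CD8+ AND CD16+"
    parent: "CD8+"
  - name: CD8+GZMB+
    expression: "CD8+ AND GZMB+"
    parent: "CD8+"
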