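# Macrophage panel: CD68, CD163, CD206, PDL1 + DAPI counterstain.
# Macrophage phenotype fractions are reported over all CD68+ and/or CD163+
# detections (any segmented object positive for either marker).
panel:
  name: macrophage
  markers:
    - {name: CD68, channel: 0, localization: cytoplasmic}
    - {name: CD163, channel: 1, localization: membranous}
    - {name: CD206, channel: 2, localization: membranous}
    - {name: PDL1, channel: 3, localization: membranous}
    - {name: DAPI, channel: 4, localization: nuclear, counterstain: true}
phenotypes:
  - name: Macrophage detection
    expression: &mac "CD68+ AND/OR CD163+"
  - name: CD163+
    expression: "CD163+ AND (CD68+ AND/OR CD163+)"
    parent: *mac
  - name: CD163+PDL1+
    expression: "CD163+ AND PDL1+"
    parent: *mac
  - name: CD68+
    expression: "CD68+ AND (CD68+ AND/OR CD163+)"
    parent: *mac
  - name: CD206+
    expression: "CD206+ AND (CD68+ AND/OR CD163+)"
    parent: *mac
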