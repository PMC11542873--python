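# Synthetic vitamin trophy rules.
#
# Module ids follow the field's vocabulary (biotin ring assembly M00123 /
# M00950; thiamine de novo M00127 and salvage M00899 or the thiMDE trio;
# cobalamin M00122 prokaryotic / M00925 eukaryotic; methionine synthases
# metE / metH), but every KO id and module definition in this package is an
# invented synthetic stand-in (K9xxxx range): no real KEGG content is
# shipped. Users point the pipeline at their own rules file with real KO
# ids to analyze real annotations.
vitamins:
  biotin:
    synthesis_modules: [M00123, M00950]
    salvage_modules: []
    gene_alternatives: {}
  thiamine:
    synthesis_modules: [M00127]
    salvage_modules: [M00899]
    gene_alternatives:
      thiMDE:
        route: salvage
        kos: [K90221, K90222, K90223]
  cobalamin:
    synthesis_modules: [M00122, M00925]
    salvage_modules: []
    gene_alternatives: {}
genes:
  metE: K90401
  metH: K90402
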