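# Example mapping from annotation products / KEGG orthologs to the marker
# families used by the built-in role rules. Mapping annotations to families
# is the upstream annotator's job; this file documents one reasonable
# mapping and can seed a custom one.
families:
  hydrogenase:
    - "K00532"   # hydrogenase large subunit (FeFe)
    - "K06281"   # hydrogenase large subunit (NiFe, hyaB)
    - "K18016"   # membrane-bound hydrogenase subunit
  scfa_transformation:
    - "K00925"   # acetate kinase (ackA)
    - "K00625"   # phosphate acetyltransferase (pta)
    - "K01034"   # acetate CoA-transferase (atoD)
    - "K00169"   # pyruvate:ferredoxin oxidoreductase alpha
  co_dehydrogenase:
    - "K00198"   # anaerobic CO dehydrogenase (cooS)
  cbiA:
    - "K02224"   # cobyrinate a,c-diamide synthase
  cobS:
    - "K02233"   # adenosylcobinamide-GDP ribazoletransferase
  cobV:
    - "K02233"
  dmb_synthase:
    - "K04719"   # 5,6-dimethylbenzimidazole synthase (bluB)
  btuB:
    - "K16092"   # vitamin B12 outer-membrane transporter
  btuC:
    - "K06073"   # vitamin B12 transport permease
  btuD:
    - "K06074"   # vitamin B12 transport ATPase
  rpfB:
    - "K17836"   # resuscitation-promoting factor RpfB
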