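# Contaminant marker panels for urine sample-quality assessment, as
# uppercase gene symbols.  A protein group counts as a panel hit when any
# of its ";"-separated members matches a panel entry.  These lists are
# editable defaults, not an authoritative clinical panel:
#   erythrocyte           - hemolysis / hematuria markers
#   cellular_debris       - intracellular and epithelial (keratin) markers
#     released by insufficient cell removal
#   serum_high_abundance  - plasma leakage markers (proteinuria)
erythrocyte:
  - HBA1
  - HBA2
  - HBB
  - HBD
  - CA1
  - CA2
  - PRDX2
  - BLVRB
  - SLC4A1
  - SPTA1
  - SPTB
  - ANK1
cellular_debris:
  - KRT1
  - KRT2
  - KRT5
  - KRT9
  - KRT10
  - KRT14
  - ACTB
  - ACTG1
  - GAPDH
  - TUBB
  - VIM
  - LDHA
  - ENO1
serum_high_abundance:
  - ALB
  - IGHG1
  - IGHG2
  - IGHG3
  - IGHG4
  - IGKC
  - TF
  - SERPINA1
  - HP
  - A2M
  - APOA1
  - APOB
  - FGA
  - FGB
  - FGG
  - C3
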