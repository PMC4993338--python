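# Risk-allele map for the 7-SNP telomere-length genetic risk score.
#
# PLACEHOLDER alleles and coordinates: the effect-allele identities were not
# published in the available study text. Edit risk_allele/other_allele (and
# chrom/pos if writing VCF) from the source GWAS before real-data use.
rs2736100:
  risk_allele: A
  other_allele: C
  source: genotyped
  chrom: "5"
  pos: 1286516
rs2281929:
  risk_allele: A
  other_allele: G
  source: genotyped
  chrom: "20"
  pos: 62436398
rs11125529:
  risk_allele: A
  other_allele: C
  source: imputed
  chrom: "2"
  pos: 54475866
rs10936599:
  risk_allele: C
  other_allele: T
  source: imputed
  chrom: "3"
  pos: 169492101
rs7675998:
  risk_allele: G
  other_allele: A
  source: imputed
  chrom: "4"
  pos: 164007820
rs9420907:
  risk_allele: C
  other_allele: A
  source: imputed
  chrom: "10"
  pos: 105676465
rs8105767:
  risk_allele: G
  other_allele: A
  source: imputed
  chrom: "19"
  pos: 22215441
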