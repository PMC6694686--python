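# Default Cas enzyme registry: 11 commonly used nucleases.
# pam_side is the PAM's position relative to the protospacer on the
# protospacer's strand (three_prime for Cas9-family, five_prime for
# Cas12a/Cpf1-family). protospacer_length defaults to 20 when omitted.
- name: SpCas9
  pam_motif: NGG
  pam_side: three_prime
- name: SpCas9-VQR
  pam_motif: NGA
  pam_side: three_prime
- name: SpCas9-VRER
  pam_motif: NGCG
  pam_side: three_prime
- name: SpCas9-EQR
  pam_motif: NGAG
  pam_side: three_prime
- name: SaCas9
  pam_motif: NNGRRT
  pam_side: three_prime
- name: SaCas9-KKH
  pam_motif: NNNRRT
  pam_side: three_prime
- name: NmeCas9
  pam_motif: NNNNGATT
  pam_side: three_prime
- name: CjCas9
  pam_motif: NNNNRYAC
  pam_side: three_prime
- name: StCas9
  pam_motif: NNAGAAW
  pam_side: three_prime
- name: AsCas12a
  pam_motif: TTTV
  pam_side: five_prime
- name: LbCas12a
  pam_motif: TTTN
  pam_side: five_prime
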