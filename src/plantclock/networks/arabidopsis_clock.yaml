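# Canonical repression-centred Arabidopsis circadian clock network.
#
# 12 transcribed genes; 35 state variables (12 mRNA, 18 protein pools,
# ELF3-ELF4 and GI-ZTL complexes, constitutive ZTL and COP1 cyt/nuc);
# 119 rate parameters (Hill exponents are fixed integers written here).
# The evening complex (EC) is an algebraic activity, not a state variable.
# "LC" denotes the summed nuclear LHY + CCA1 pool acting inside one Hill
# term.  The only activator is RVE8; light enters through one acute
# transcriptional term (PRR9), the light-gated GI-ZTL complex cycle,
# dark-gated COP1 nuclear import, and dark ZTL-mediated degradation of
# TOC1 and PRR5.
name: arabidopsis-clock-core
genes:
  LHY:  {compartments: [c, n]}
  CCA1: {compartments: [c, n]}
  PRR9: {compartments: [n], acute_light: a_PRR9}
  PRR7: {compartments: [n]}
  PRR5: {compartments: [c, n]}
  TOC1: {compartments: [c, n]}
  RVE8: {compartments: [n]}
  GI:   {compartments: [c, n]}
  NOX:  {compartments: [n]}
  LUX:  {compartments: [n]}
  ELF3: {compartments: [c, n]}
  ELF4: {compartments: [n]}

pseudo_regulators:
  LC: [LHY_n, CCA1_n]

edges:
  # the PRR wave represses the morning genes (independent K per target)
  - {regulator: PRR9, target: LHY, h: 2}
  - {regulator: PRR7, target: LHY, h: 2}
  - {regulator: PRR5, target: LHY, h: 2}
  - {regulator: TOC1, target: LHY, h: 2}
  - {regulator: PRR9, target: CCA1, h: 2}
  - {regulator: PRR7, target: CCA1, h: 2}
  - {regulator: PRR5, target: CCA1, h: 2}
  - {regulator: TOC1, target: CCA1, h: 2}
  # PRR wave internal repression: TOC1 represses the earlier PRRs and
  # itself; PRR5 represses PRR9 and PRR7; no activation anywhere
  - {regulator: TOC1, target: PRR9, h: 2}
  - {regulator: PRR5, target: PRR9, h: 2}
  - {regulator: TOC1, target: PRR7, h: 2}
  - {regulator: PRR5, target: PRR7, h: 2}
  - {regulator: TOC1, target: PRR5, h: 2}
  - {regulator: TOC1, target: TOC1, h: 2}
  # CCA1/LHY (summed pool) repress the later PRRs but not PRR9
  - {regulator: LC, target: PRR7, h: 2}
  - {regulator: LC, target: PRR5, h: 2}
  - {regulator: LC, target: TOC1, h: 2}
  # evening complex represses the PRR wave and the evening genes
  - {regulator: EC, target: PRR9, h: 2}
  - {regulator: EC, target: PRR7, h: 2}
  - {regulator: EC, target: PRR5, h: 2}
  - {regulator: EC, target: TOC1, h: 2}
  - {regulator: EC, target: GI, h: 2}
  - {regulator: EC, target: LUX, h: 2}
  - {regulator: EC, target: ELF4, h: 2}
  # CCA1/LHY repress the evening genes
  - {regulator: LC, target: GI, h: 2}
  - {regulator: LC, target: LUX, h: 2}
  - {regulator: LC, target: ELF4, h: 2}
  - {regulator: LC, target: ELF3, h: 2}
  # RVE8 is repressed by the day PRRs
  - {regulator: PRR9, target: RVE8, h: 2}
  - {regulator: PRR7, target: RVE8, h: 2}
  - {regulator: PRR5, target: RVE8, h: 2}
  # NOX is repressed by PRR7
  - {regulator: PRR7, target: NOX, h: 2}
  # RVE8 activates six targets (evening genes plus PRR9)
  - {regulator: RVE8, target: PRR9, mode: activation, h: 2}
  - {regulator: RVE8, target: PRR5, mode: activation, h: 2}
  - {regulator: RVE8, target: TOC1, mode: activation, h: 2}
  - {regulator: RVE8, target: GI,   mode: activation, h: 2}
  - {regulator: RVE8, target: LUX,  mode: activation, h: 2}
  - {regulator: RVE8, target: ELF4, mode: activation, h: 2}

ec:
  lux: LUX_n
  nox: NOX_n
  complex: E34_n
  free_elf3: ELF3_n
  h: 2

complexes:
  E34_n:
    components: [ELF3_n, ELF4_n]
    assoc: ka_E34
    deg: d_E34
  ZG_c:
    components: [GI_c, ZTL_c]
    assoc: ka_ZG
    assoc_gate: light
    dissoc: kd_ZG
    dissoc_gate: dark
    deg: d_ZG

constitutive:
  ZTL_c:
    production: p_ZTL
    degradation: d_ZTL
  COP1_c:
    production: p_COP1
    degradation: dc_COP1
    transport: {to: COP1_n, rate: t_COP1, gate: dark}
  COP1_n:
    degradation: dn_COP1

mediated_degradation:
  - {enzyme: ZTL_c,  substrate: TOC1_c, rate: m_ZTL_TOC1, gate: dark}
  - {enzyme: ZTL_c,  substrate: PRR5_c, rate: m_ZTL_PRR5, gate: dark}
  - {enzyme: COP1_c, substrate: ELF3_c, rate: m_COP1_ELF3c}
  - {enzyme: COP1_n, substrate: ELF3_n, rate: m_COP1_ELF3n}
  - {enzyme: COP1_n, substrate: GI_n,   rate: m_COP1_GIn}

# parameters not released to the optimizer: the COP1 block plus the
# ZTL/GI protein machinery (GI production and transport stay free)
hand_constrained:
  [p_COP1, dc_COP1, t_COP1, dn_COP1, m_COP1_ELF3c, m_COP1_ELF3n, m_COP1_GIn,
   p_ZTL, d_ZTL, ka_ZG, kd_ZG, d_ZG, m_ZTL_TOC1, m_ZTL_PRR5, dp_GI, dp_TOC1]
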