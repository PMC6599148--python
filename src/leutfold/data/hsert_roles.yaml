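# Residue role map for the human serotonin transporter (hSERT, UniProt P31645),
# chain A, author numbering as deposited in the X-ray/cryo-EM entries.
#
# Transmembrane-helix boundaries are APPROXIMATE: they derive from topology
# annotation of the transporter fold (helix assignments of the resolved
# structures), and are intended to be edited for a given analysis.  The
# functional roles (gates, binding-site anchors, vestibule limits) are the
# conserved, published residue assignments.
chain: A
roles:
  TM1a: [[80, 97]]
  TM1b: [[101, 119]]
  TM2: [[124, 153]]
  TM3: [[158, 193]]
  TM4: [[239, 260]]
  TM5: [[265, 290]]
  TM6a: [[322, 337]]
  TM6b: [[342, 356]]
  TM7: [[366, 393]]
  TM8: [[425, 455]]
  TM9: [[461, 484]]
  TM10: [[488, 516]]
  TM11: [[525, 552]]
  TM12: [[558, 584]]
  # hash = quasi-static scaffold (TM3 + TM4 + TM8 + TM9), the superposition frame
  hash: [[158, 193], [239, 260], [425, 455], [461, 484]]
  # extracellular gates: R104-E493 salt bridge, Y176-F335 hydrophobic lid
  EC_gate_salt: [104, 493]
  EC_gate_lid: [176, 335]
  # intracellular gate network, as consecutive pairs:
  # R79-D452, W82-Y350, Y350-E444, E444-R462
  IC_gate_pairs: [79, 452, 82, 350, 350, 444, 444, 462]
  # residues coordinating the substrate's primary amine: Y95, D98, F335, S336
  amine_partners: [95, 98, 335, 336]
  # orthosteric-site anchors: extracellular lid (Y176, F335), cytoplasmic F341
  site_anchors_ec: [176, 335]
  site_anchor_cyt: [341]
  # vestibule limits: extracellular to R104/E493, intracellular to L89/S277
  ec_vestibule_limit: [104, 493]
  ic_vestibule_limit: [89, 277]
  EL2_range: [[194, 238]]
  termini_ranges: [[74, 79], [601, 617]]
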