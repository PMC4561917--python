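# Fragment scheme: chlorophyll a (reduced heavy-atom set, synthetic frames).
#
# Atom labels follow the IUPAC porphyrin convention (C1..C20 macrocycle,
# N21..N24, meso carbons C5/C10/C15/C20); first side-chain heavy atoms are
# suffixed _1.  The four quadrant fragments cover the molecule: the meso
# carbons are split 1/2 between adjacent fragments and the central Mg 1/4
# between all four, so the fragments partition any normalised frame exactly.
# Fragments 1 and 3 lie along the Gouterman x-axis, 2 and 4 along y.
species: chla
atoms: [Mg, N21, N22, N23, N24,
        C1, C2, C3, C4, C5, C6, C7, C8, C9, C10,
        C11, C12, C13, C14, C15, C16, C17, C18, C19, C20,
        C2_1, C3_1, C7_1, C8_1, C12_1, C13_1, C18_1, O13_1]
groups:
  Mg: {Mg: 1}
  N4: {N21: 1, N22: 1, N23: 1, N24: 1}
  O13_1: {O13_1: 1}
  inner_macrocycle: {C1: 1, C4: 1, C5: 1, C6: 1, C9: 1, C10: 1,
                     C11: 1, C14: 1, C15: 1, C16: 1, C19: 1, C20: 1}
  outer_macrocycle: {C2: 1, C3: 1, C7: 1, C8: 1, C12: 1, C13: 1, C17: 1, C18: 1}
  fragment_1: {C16: 1, C17: 1, C18: 1, C19: 1, N24: 1, C18_1: 1,
               C15: 0.5, C20: 0.5, Mg: 0.25}
  fragment_2: {C1: 1, C2: 1, C3: 1, C4: 1, N21: 1, C2_1: 1, C3_1: 1,
               C5: 0.5, C20: 0.5, Mg: 0.25}
  fragment_3: {C6: 1, C7: 1, C8: 1, C9: 1, N22: 1, C7_1: 1, C8_1: 1,
               C5: 0.5, C10: 0.5, Mg: 0.25}
  fragment_4: {C11: 1, C12: 1, C13: 1, C14: 1, N23: 1, C12_1: 1, C13_1: 1,
               O13_1: 1, C10: 0.5, C15: 0.5, Mg: 0.25}
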