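# RECAP retrosynthetic bond-cleavage rules.
#
# Each rule is a SMARTS pattern in which atom maps :1 and :2 mark the two
# atoms of the bond to be cleaved.  Only acyclic bonds are ever cut (ring
# bonds are skipped even if a pattern matches them).  The eleven entries
# correspond to the classical RECAP bond types: amide, ester, amine, urea,
# ether, olefin, quaternary nitrogen, aromatic N - aliphatic C, lactam N -
# aliphatic C, aromatic C - aromatic C (biaryl) and sulfonamide.
#
# Dialect notes, made explicit here so they are auditable and overridable:
#   * the amide rule requires a carbon substituent on the carbonyl, so the
#     N-C bond of a urea is cleaved by the urea rule only;
#   * the amine rule excludes amide/sulfonamide nitrogens (those N-C bonds
#     are not amine bonds) and nitrogens bound to heteroatoms;
#   * the ether rule excludes the ester oxygen (cleaved by the ester rule
#     at the acyl bond instead) and only cuts O-C(aliphatic) bonds;
#   * the biaryl rule [c:1]-!@[c:2] requires BOTH atoms aromatic, i.e. both
#     in (different) aromatic rings: exocyclic aromatic-aliphatic bonds are
#     never cut by it.  Edit or remove the entry to change this behaviour.
rules:
  - id: amide
    smarts: "[C;$(C([#6])=O):1](=O)-!@[N;!$(N=*):2]"
  - id: ester
    smarts: "[C;$(C([#6])=O):1](=O)-!@[O;$(O[#6]);X2:2]"
  - id: amine
    smarts: "[N;X3;!$(N=*);!$(N[C,S]=[O,S,N]);!$(N~[!#6;!#1]):1]-!@[C;X4:2]"
  - id: urea
    smarts: "[N;!$(N=*):1]-!@[C;$(C(=O)([#7])[#7]):2]"
  - id: ether
    smarts: "[O;X2;$(O([#6])[#6]);!$(OC=[O,S,N]):1]-!@[C:2]"
  - id: olefin
    smarts: "[C;X3;!$(C=[O,N,S]):1]=!@[C;X3;!$(C=[O,N,S]):2]"
  - id: quaternary_n
    smarts: "[N;X4;+:1]-!@[C:2]"
  - id: aromatic_n_aliphatic_c
    smarts: "[n:1]-!@[C;X4:2]"
  - id: lactam_n_aliphatic_c
    smarts: "[N;R;$(N[C;R]=O):1]-!@[C;X4:2]"
  - id: aromatic_c_aromatic_c
    smarts: "[c:1]-!@[c:2]"
  - id: sulfonamide
    smarts: "[N;!$(N=*):1]-!@[S;$(S(=O)(=O)):2]"
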