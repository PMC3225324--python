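# Default base substructure set Z (49 patterns) for the substructure-pair
# descriptor. Three categories: per-residue atom counts binarized by a
# threshold, presence/absence substructure patterns (SMARTS), and relational
# "property" patterns (SMARTS paths joining two chemotypes through linker
# atoms). Patterns are evaluated on the monomer with its
# attachment dummies in place (the residue in its in-chain context). This set is a documented reconstruction: any
# alternative base set with the same schema can be loaded in its place.
patterns:
  # ---- atom counts (9 classes: Cl, F, N, O, C, aromatic C, S, aromatic N,
  # and all remaining heavy atoms). A bit fires when the residue holds at
  # least `threshold` atoms of the class; thresholds above 1 discount the
  # atoms every backbone contributes.
  - id: n_cl
    category: atom_count
    atom_class: Cl
    threshold: 1
    description: at least one chlorine atom
  - id: n_f
    category: atom_count
    atom_class: F
    threshold: 1
    description: at least one fluorine atom
  - id: n_n
    category: atom_count
    atom_class: N
    threshold: 2
    description: at least two non-aromatic nitrogens (side chain beyond the backbone amine)
  - id: n_o
    category: atom_count
    atom_class: O
    threshold: 2
    description: at least two oxygens (side chain beyond the backbone carbonyl)
  - id: n_c
    category: atom_count
    atom_class: C
    threshold: 5
    description: at least five non-aromatic carbons
  - id: n_c_aromatic
    category: atom_count
    atom_class: C_aromatic
    threshold: 1
    description: at least one aromatic carbon
  - id: n_s
    category: atom_count
    atom_class: S
    threshold: 1
    description: at least one sulfur atom
  - id: n_n_aromatic
    category: atom_count
    atom_class: N_aromatic
    threshold: 1
    description: at least one aromatic nitrogen
  - id: n_other
    category: atom_count
    atom_class: other
    threshold: 1
    description: at least one heavy atom outside the eight named classes

  # ---- substructures (28 presence/absence SMARTS)
  - id: hydroxyl
    category: substructure
    smarts: "[OX2H]"
    description: hydroxyl group
  - id: phenol
    category: substructure
    smarts: "c[OX2H]"
    description: hydroxyl on an aromatic carbon
  - id: carboxylic_acid
    category: substructure
    smarts: "[CX3](=O)[OX2H1]"
    description: carboxylic acid
  - id: primary_amide
    category: substructure
    smarts: "[CX3](=O)[NX3H2]"
    description: primary carboxamide
  - id: amide
    category: substructure
    smarts: "[CX3](=O)[NX3]"
    description: any amide linkage
  - id: primary_amine
    category: substructure
    smarts: "[NX3H2;!$(NC=O)]"
    description: primary amine (not amide)
  - id: secondary_amine
    category: substructure
    smarts: "[NX3H1;!$(NC=O)]"
    description: secondary amine (not amide)
  - id: guanidine
    category: substructure
    smarts: "[NX3][CX3](=[NX2])[NX3]"
    description: guanidine group
  - id: imidazole
    category: substructure
    smarts: "c1cnc[nH]1"
    description: imidazole ring
  - id: indole
    category: substructure
    smarts: "c1ccc2c(c1)cc[nH]2"
    description: indole ring system
  - id: phenyl
    category: substructure
    smarts: "c1ccccc1"
    description: six-membered aromatic carbocycle
  - id: thiol
    category: substructure
    smarts: "[SX2H]"
    description: thiol
  - id: thioether
    category: substructure
    smarts: "[SX2]([#6])[#6]"
    description: thioether
  - id: methyl
    category: substructure
    smarts: "[CX4H3]"
    description: methyl group
  - id: methylene
    category: substructure
    smarts: "[CX4H2]"
    description: methylene group
  - id: gem_dimethyl
    category: substructure
    smarts: "[CX4H]([CH3])[CH3]"
    description: isopropyl-type branch point
  - id: ethylene_chain
    category: substructure
    smarts: "[CX4H2][CX4H2]"
    description: two consecutive methylenes
  - id: propylene_chain
    category: substructure
    smarts: "[CX4H2][CX4H2][CX4H2]"
    description: three consecutive methylenes
  - id: halogen
    category: substructure
    smarts: "[F,Cl,Br,I]"
    description: any halogen
  - id: aryl_halide
    category: substructure
    smarts: "c[F,Cl,Br,I]"
    description: halogen on an aromatic carbon
  - id: hydroxymethyl
    category: substructure
    smarts: "[CX4][OX2H]"
    description: aliphatic carbon bearing a hydroxyl
  - id: branched_carbon
    category: substructure
    smarts: "[CX4H1]([#6])([#6])[#6]"
    description: tertiary aliphatic CH
  - id: pyridine_n
    category: substructure
    smarts: "[nX2]"
    description: pyridine-type aromatic nitrogen
  - id: carbonyl
    category: substructure
    smarts: "[CX3]=[OX1]"
    description: carbonyl group
  - id: ether
    category: substructure
    smarts: "[OD2]([#6])[#6]"
    description: ether/ester oxygen between two carbons
  - id: amidine
    category: substructure
    smarts: "[NX2]=[CX3][NX3]"
    description: amidine fragment
  - id: aliphatic_ring
    category: substructure
    smarts: "[C;R]"
    description: carbon in a non-aromatic ring
  - id: fused_ring_atom
    category: substructure
    smarts: "[R2]"
    description: atom shared by two rings

  # ---- properties (12 relational SMARTS: two chemotypes joined through
  # linker atoms; `~` is any bond). The first reproduces the canonical
  # example of a methylene and a hydrogen-bond acceptor connected via any
  # single atom.
  - id: methylene_linker_acceptor
    category: property
    smarts: "[CX4H2]~*~[OX1,OX2,NX2,nX2]"
    description: methylene and H-bond acceptor connected via any atom
  - id: donor_linker_acceptor
    category: property
    smarts: "[OX2H,NX3H2]~*~[OX1,NX2]"
    description: H-bond donor and acceptor separated by one atom
  - id: aromatic_linker_donor
    category: property
    smarts: "a~*~[OX2H,NX3H2]"
    description: aromatic atom and H-bond donor separated by one atom
  - id: methyl_linker_aromatic
    category: property
    smarts: "[CX4H3]~*~a"
    description: methyl and aromatic atom separated by one atom
  - id: donor_pair_short
    category: property
    smarts: "[OX2H,NX3H2,SX2H]~*~[OX2H,NX3H2,SX2H]"
    description: two H-bond donors within two bonds
  - id: acceptor_pair_spaced
    category: property
    smarts: "[OX1,NX2]~*~*~[OX1,NX2]"
    description: two H-bond acceptors separated by two atoms
  - id: methylene_chain_to_aromatic
    category: property
    smarts: "[CX4H2]~[CX4H2]~a"
    description: two-methylene hydrophobic link into an aromatic system
  - id: methyl_spaced_donor
    category: property
    smarts: "[CX4H3]~*~*~[OX2H,NX3H2]"
    description: methyl and H-bond donor separated by two atoms
  - id: halogen_linker_aromatic
    category: property
    smarts: "[F,Cl,Br,I]~*~a"
    description: halogen one atom away from an aromatic system
  - id: sulfur_linker_methyl
    category: property
    smarts: "[SX2]~*~[CX4H3]"
    description: divalent sulfur one atom away from a methyl
  - id: aromatic_acceptor_contact
    category: property
    smarts: "a~[OX1,OX2,NX2]"
    description: H-bond acceptor directly on an aromatic atom
  - id: twin_methyl
    category: property
    smarts: "[CX4H3]~*~[CX4H3]"
    description: two methyls on a common neighbourhood
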