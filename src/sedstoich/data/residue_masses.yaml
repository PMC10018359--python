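# Average (isotope-abundance-weighted) residue masses, g/mol.
#
# peptide: residue = amino acid minus one water; a chain gains one terminal
#   water (free N/C termini, no modifications).
# ssDNA: residue = 2'-deoxynucleoside-5'-monophosphate minus one water
#   (the repeating unit of the phosphodiester backbone); the documented end
#   chemistry is 5'-OH / 3'-OH, so a chain gains one water and loses one
#   HPO3 (79.98) relative to the plain residue sum, i.e. terminal_correction
#   = 18.02 - 79.98 = -61.96.
# adducts: masses added by covalent labels. Cy3 is the phosphoramidite-
#   coupled cyanine-3 label including its linker phosphate.
peptide:
  terminal_correction: 18.02
  residues:
    G: 57.05
    A: 71.08
    S: 87.08
    P: 97.12
    V: 99.13
    T: 101.10
    C: 103.14
    L: 113.16
    I: 113.16
    N: 114.10
    D: 115.09
    Q: 128.13
    K: 128.17
    E: 129.12
    M: 131.19
    H: 137.14
    F: 147.18
    R: 156.19
    Y: 163.18
    W: 186.21
ssDNA:
  terminal_correction: -61.96
  residues:
    A: 313.21
    C: 289.18
    G: 329.21
    T: 304.20
adducts:
  Cy3: 507.66
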