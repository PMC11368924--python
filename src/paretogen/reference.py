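"""Canonical free-base structures of the case-study reference drugs.

Tropifexor is the farnesoid X receptor (FXR) agonist used against
non-alcoholic fatty liver disease; its co-crystal with FXR is PDB
entry 7D42.  Copanlisib is the PI3K inhibitor approved for follicular
lymphoma; its co-crystal with PI3K-gamma is PDB entry 5G2N.  The
SMILES below are the canonical free-base forms (molecular formulas
C29H25F4N3O5S and C23H28N8O4 respectively), kept in-repo so descriptor
regression checks need no structure download.
"""

REFERENCE_LIGANDS: dict[str, str] = {
    # 2-[(3S)-3-({5-cyclopropyl-3-[2-(trifluoromethoxy)phenyl]-1,2-oxazol-4-yl}
    # methoxy)-8-azabicyclo[3.2.1]octan-8-yl]-4-fluoro-1,3-benzothiazole-6-
    # carboxylic acid
    "tropifexor": (
        "OC(=O)c1cc(F)c2nc(N3C4CCC3CC(C4)OCc3c(-c5ccccc5OC(F)(F)F)noc3C3CC3)sc2c1"
    ),
    # 2-amino-N-[7-methoxy-8-(3-morpholin-4-ylpropoxy)-2,3-dihydroimidazo
    # [1,2-c]quinazolin-5-yl]pyrimidine-5-carboxamide
    "copanlisib": (
        "COC1=C(C=CC2=C1N3CCN=C3N=C2NC(=O)C4=CN=C(N=C4)N)OCCCN5CCOCC5"
    ),
}
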