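"""Reference data for ribavirin and its structural analogues.

Literature-compiled characterization data used as worked examples and test
inputs: experimental ¹⁴N NQR frequencies of crystalline ribavirin and of
1H-1,2,4-triazole, DFT-derived NQR parameters per nitrogen site in three
contexts (single molecule, solid, protein–ligand complex), docking energy
decompositions against the SARS-CoV-2 RdRp target, binding affinities,
ligand–ribavirin similarity scores, and nitrogen-localized Hirshfeld
contact-surface contributions.  Frequencies and coupling constants are in
MHz, energies in kJ/mol, contact contributions in percent.
"""

from __future__ import annotations

from .contact_stats import ContributionVector
from .nqr import NQRParams
from .quad_indices import ContextParams
from .sbsi import EnergyDecomposition, SimilarityScores

__all__ = [
    "RIBAVIRIN_NQR_LINES",
    "TRIAZOLE_NQR_LINES",
    "SOLID_STATE_CONTEXTS",
    "COMPLEXATION_CONTEXTS",
    "solid_vs_complex_contexts",
    "DOCKING_ENERGIES",
    "BINDING_AFFINITIES",
    "SIMILARITY_SCORES",
    "NITROGEN_CONTACT_CHANNELS",
    "NITROGEN_CONTACTS",
    "LIGAND_SMILES",
    "energy_decompositions",
    "similarity_scores",
    "nitrogen_contact_vector",
]

#: Experimental ¹⁴N NQR transition frequencies of crystalline ribavirin at
#: 295 K: site label -> (ν₊, ν₋, ν₀) in MHz, with the site assignment.
RIBAVIRIN_NQR_LINES = {
    "N(1)": {"triplet": (2.340, 1.700, 0.640), "assignment": "-NH2"},
    "N(2)": {"triplet": (3.980, 2.650, 1.330), "assignment": "-N= ring position N(2)"},
    "N(3)": {"triplet": (2.600, 2.280, 0.320), "assignment": "-N= ring position N(4)"},
    "N(4)": {"triplet": (2.400, 1.480, 0.920), "assignment": ">N-sugar"},
}

#: Room-temperature ¹⁴N NQR frequencies of 1H-1,2,4-triazole (the aglycone
#: core of ribavirin): site -> (ν₊, ν₋, ν₀) in MHz.  The listed ν₀ for N(2)
#: differs from ν₊ − ν₋ by 0.004 MHz; ν₊ and ν₋ are primary.
TRIAZOLE_NQR_LINES = {
    "N(2)": (3.793, 2.405, 1.384),
    "N(4)": (2.503, 2.257, 0.246),
    ">NH": (2.114, 1.442, 0.672),
}

#: DFT-derived NQR parameters (|e²qQ/h| MHz, η) per nitrogen site: solid
#: state and the single molecule extracted from the same crystal.
SOLID_STATE_CONTEXTS = {
    "RBV form I": {
        "-NH2": {"solid": (3.288, 0.030), "single": (3.946, 0.110)},
        "N(2)": {"solid": (3.947, 0.930), "single": (4.142, 0.680)},
        "N(4)": {"solid": (3.188, 0.370), "single": (3.926, 0.090)},
        ">N-sugar": {"solid": (2.490, 0.851), "single": (2.649, 0.730)},
    },
    "RBV form II": {
        "-NH2": {"solid": (2.629, 0.750), "single": (3.758, 0.070)},
        "N(2)": {"solid": (4.513, 0.640), "single": (4.527, 0.660)},
        "N(4)": {"solid": (3.516, 0.020), "single": (4.063, 0.130)},
        ">N-sugar": {"solid": (2.852, 0.511), "single": (2.734, 0.670)},
    },
    "FVP form I": {
        "-NH2": {"solid": (2.336, 0.81), "single": (2.968, 0.51)},
        "N(4)": {"solid": (4.56, 0.24), "single": (4.829, 0.32)},
        "N(1)": {"solid": (4.739, 0.35), "single": (4.564, 0.33)},
    },
    "FVP form II": {
        "-NH2": {"solid": (2.308, 0.76), "single": (2.935, 0.48)},
        "N(4)": {"solid": (4.615, 0.34), "single": (4.839, 0.4)},
        "N(1)": {"solid": (4.676, 0.38), "single": (4.554, 0.39)},
    },
}

#: NQR parameters in the protein–ligand complex vs the single molecule
#: (complex-phase geometry), per ligand and nitrogen site.
COMPLEXATION_CONTEXTS = {
    "RBV": {
        "-NH2": {"complex": (2.742, 0.610), "single": (4.212, 0.230)},
        "N(2)": {"complex": (4.810, 0.630), "single": (4.662, 0.650)},
        "N(4)": {"complex": (4.519, 0.090), "single": (4.525, 0.070)},
        ">N-sugar": {"complex": (2.842, 0.511), "single": (2.850, 0.640)},
    },
    "FVP-R": {
        "-NH2": {"complex": (2.445, 0.300), "single": (3.810, 0.120)},
        "N(4)": {"complex": (4.637, 0.420), "single": (4.784, 0.400)},
        "N(1)": {"complex": (1.989, 0.180), "single": (2.283, 0.400)},
    },
}


def solid_vs_complex_contexts(ligand: str, form: str) -> list[ContextParams]:
    """Join complex-context and solid-context parameters per shared site.

    ``ligand`` keys COMPLEXATION_CONTEXTS, ``form`` keys
    SOLID_STATE_CONTEXTS; only sites present in both are joined (site
    aliasing across chemically different positions is never silent).
    """
    comp = COMPLEXATION_CONTEXTS[ligand]
    solid = SOLID_STATE_CONTEXTS[form]
    out = []
    for site in comp:
        if site not in solid:
            continue
        out.append(
            ContextParams(
                site_label=site,
                solid=NQRParams(*solid[site]["solid"]),
                complex=NQRParams(*comp[site]["complex"]),
            )
        )
    return out


#: Docking energy decomposition per ligand (kJ/mol), SARS-CoV-2 RdRp target
#: with the ligand incorporated into the RNA primer.
DOCKING_ENERGIES = {
    "T-705":     {"total": -498.80, "protein_ligand": -191.67, "steric": -134.72,
                  "hydrogen_bonds": -21.75, "vdw": -55.00, "metal": -40.47,
                  "rna_template": -292.90},
    "T-1106":    {"total": -496.06, "protein_ligand": -188.93, "steric": -135.66,
                  "hydrogen_bonds": -18.06, "vdw": -55.00, "metal": -40.47,
                  "rna_template": -266.65},
    "RBV":       {"total": -448.26, "protein_ligand": -207.44, "steric": -155.14,
                  "hydrogen_bonds": -19.28, "vdw": -60.55, "metal": -42.95,
                  "rna_template": -197.87},
    "Inosine":   {"total": -402.65, "protein_ligand": -200.96, "steric": -150.54,
                  "hydrogen_bonds": -16.50, "vdw": -44.85, "metal": -42.95,
                  "rna_template": -202.59},
    "Acadesine": {"total": -402.98, "protein_ligand": -203.64, "steric": -156.29,
                  "hydrogen_bonds": -14.32, "vdw": -50.66, "metal": -42.95,
                  "rna_template": -199.08},
    "Guanosine": {"total": -383.74, "protein_ligand": -177.36, "steric": -138.14,
                  "hydrogen_bonds": -6.19, "vdw": -60.69, "metal": -42.95,
                  "rna_template": -206.89},
}

#: Estimated binding affinity per ligand (kJ/mol), separate from the
#: decomposition terms.
BINDING_AFFINITIES = {
    "T-705": -71.98,
    "T-1106": -68.51,
    "RBV": -50.34,
    "Inosine": -31.43,
    "Acadesine": -29.84,
    "Guanosine": -27.13,
}

#: Similarity of each ligand to ribavirin: (fingerprint Tanimoto, atom-pair
#: Tanimoto, maximum-common-substructure similarity).
SIMILARITY_SCORES = {
    "RBV": (1.0, 1.0, 1.0),
    "Guanosine": (0.4476, 0.598, 0.5417),
    "Inosine": (0.4526, 0.560, 0.5652),
    "Acadesine": (0.4675, 0.731, 0.8421),
    "T-705": (0.4342, 0.545, 0.4231),
    "T-1106": (0.4298, 0.615, 0.4400),
}

#: The five nitrogen-localized Hirshfeld contact channels.
NITROGEN_CONTACT_CHANNELS = ("N...C", "N...H", "N...N", "N...O", "N...F")

#: Percentage contributions to the nitrogen-localized Hirshfeld surface per
#: structure; a channel involving an element absent from the crystal is a
#: genuine zero.
NITROGEN_CONTACTS = {
    "Ribavirin form I":   (38.1, 60.3, 0.0, 1.6, 0.0),
    "Ribavirin form II":  (43.6, 51.5, 3.2, 1.8, 0.0),
    "T-705":              (45.3, 51.4, 0.0, 1.7, 1.6),
    "T-1106":             (45.3, 52.7, 0.0, 2.0, 0.0),
    "Favipiravir form I": (43.2, 48.2, 3.1, 3.0, 2.4),
    "Favipiravir form II": (44.5, 47.1, 3.1, 3.2, 2.1),
    "1H-1,2,4-triazole":  (39.5, 39.2, 21.3, 0.0, 0.0),
    "1H-1,2,4-triazole-3-carboxamide": (33.2, 63.7, 3.2, 0.0, 0.0),
    "Inosine alpha":      (56.6, 42.7, 0.3, 0.4, 0.0),
    "Inosine beta":       (59.4, 33.3, 0.5, 6.8, 0.0),
    "Acadesine":          (39.4, 59.7, 0.2, 0.7, 0.0),
    "Guanosine hydrate":  (50.8, 48.2, 0.7, 0.3, 0.0),
}

#: Ligand structures (implicit-hydrogen SMILES).
LIGAND_SMILES = {
    "RBV": "NC(=O)c1ncn(n1)C1OC(CO)C(O)C1O",
    "Guanosine": "Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1",
    "Inosine": "O=c1[nH]cnc2c1ncn2C1OC(CO)C(O)C1O",
    "Acadesine": "NC(=O)c1ncn(C2OC(CO)C(O)C2O)c1N",
    "T-705": "NC(=O)C1=NC=C(F)N(C2OC(CO)C(O)C2O)C1=O",
    "T-1106": "NC(=O)C1=NC=CN(C2OC(CO)C(O)C2O)C1=O",
    "Favipiravir": "NC(=O)c1nc(F)cnc1O",
    "1H-1,2,4-triazole": "c1nc[nH]n1",
}


def energy_decompositions() -> dict[str, EnergyDecomposition]:
    """DOCKING_ENERGIES and BINDING_AFFINITIES as EnergyDecomposition objects."""
    return {
        lig: EnergyDecomposition(
            ligand_id=lig,
            binding_affinity=BINDING_AFFINITIES[lig],
            **terms,
        )
        for lig, terms in DOCKING_ENERGIES.items()
    }


def similarity_scores() -> dict[str, SimilarityScores]:
    return {
        lig: SimilarityScores(ligand_id=lig, tanimoto=t, atom_pair=ap, mcs=m)
        for lig, (t, ap, m) in SIMILARITY_SCORES.items()
    }


def nitrogen_contact_vector(structure: str) -> ContributionVector:
    values = NITROGEN_CONTACTS[structure]
    return ContributionVector(
        channels=dict(zip(NITROGEN_CONTACT_CHANNELS, values)),
        structure_id=structure,
    )
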