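"""Published worked-example data for Danggui-Shaoyao-San (DSS).

The nine key anti-Alzheimer ingredients reported for the six-herb DSS
formula, with their published molecular weight, AlogP, H-bond acceptor
and donor counts, ADMET-classifier positive probabilities (human
intestinal absorption, blood-brain barrier) and network-model
disease-association q-values.  These rows serve as a desk-scale worked
example for the four-step screen.

The typeset source merges the ferulic-acid H-BA/H-BD cells into a
single printed digit; that row is resolved here from the compound's
structure (2 phenol/carboxyl donors, 4 oxygen acceptors) and flagged
``hbond_resolved_from_structure``.  Every chemically possible reading
passes the Rule-of-Five gate, so downstream results do not depend on
the resolution.
"""

from __future__ import annotations

from .datamodel import AdmetScores, CompoundRecord, PhyschemProfile

__all__ = ["dss_key_ingredients", "dss_key_ingredient_qvalues", "DSS_HERBS"]

#: herb codes of the DSS formula with their compositional role
DSS_HERBS = {
    "DG": ("Angelicae Sinensis Radix", "JunChen"),
    "CX": ("Chuanxiong Rhizoma", "JunChen"),
    "BS": ("Paeoniae Radix Alba", "JunChen"),
    "FL": ("Poria", "ZuoShi"),
    "ZX": ("Alismatis Rhizoma", "ZuoShi"),
    "BZ": ("Atractylodis Macrocephalae Rhizoma", "ZuoShi"),
}

# (cid, name, hia, bbb, mw, alogp, hba, hbd, q)
_ROWS = [
    ("445858", "Ferulic acid", 0.96, 0.60, 194.19, 1.53, 4, 2, 6.76e-3),
    ("5321018", "Atractylenolide I", 0.99, 0.97, 230.31, 3.51, 2, 0, 9.72e-3),
    ("5319022", "Ligustilide", 1.0, 0.99, 190.24, 2.87, 2, 0, 6.76e-3),
    ("14296", "Tetramethylpyrazine", 0.99, 1.0, 136.2, 1.71, 2, 0, 9.72e-4),
    ("11521428", "Senkyunolide I", 0.94, 0.81, 224.26, 1.04, 4, 2, 6.76e-3),
    ("3085257", "Senkyunolide A", 1.0, 0.99, 192.26, 2.75, 2, 0, 3.68e-2),
    ("370", "Gallic acid", 0.78, 0.53, 170.12, 0.5, 4, 4, 1.36e-4),
    ("61361", "3-butylphthalide", 1.0, 0.99, 190.24, 3.09, 2, 0, 6.76e-3),
    ("642376", "Z-butylidenephthalide", 1.0, 0.99, 188.23, 3.0, 2, 0, 6.76e-3),
]

#: rows whose H-bond counts were reconstructed from structure, not read
hbond_resolved_from_structure = {"445858"}


def dss_key_ingredients() -> list[CompoundRecord]:
    """The nine key DSS ingredients as fully annotated compound records."""
    return [
        CompoundRecord(
            compound_id=cid,
            name=name,
            physchem=PhyschemProfile(mw=mw, alogp=alogp, hbd=hbd, hba=hba),
            admet=AdmetScores(hia_prob=hia, bbb_prob=bbb),
        )
        for cid, name, hia, bbb, mw, alogp, hba, hbd, _ in _ROWS
    ]


def dss_key_ingredient_qvalues() -> dict[str, float]:
    """Published network-model q-values for the nine ingredients."""
    return {cid: q for cid, _, _, _, _, _, _, _, q in _ROWS}
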