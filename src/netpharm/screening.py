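"""Four-step prescription-simplification screen.

A compound is retained as a key active ingredient when it passes all
four gates in conjunction: (1) it is a main component of the formula by
HPLC, (2) it satisfies Lipinski's Rule of Five, (3) its predicted human
intestinal absorption and blood-brain barrier positive probabilities
both clear a threshold, and (4) its disease-enrichment q-value is below
the significance level.

Each gate is a pure predicate; missing input data makes a compound
*ineligible* for that gate (``None``) rather than failing it, so
curation gaps remain visible in the audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .datamodel import AdmetScores, CompoundRecord, PhyschemProfile
from .enrichment import EnrichmentRecord

log = logging.getLogger(__name__)

__all__ = [
    "ScreenDecision",
    "SimplificationReport",
    "lipinski_pass",
    "admet_gate",
    "four_step_screen",
]

#: Lipinski Rule-of-Five bounds (all strict, as conventionally printed)
RO5_MW_MAX = 500.0
RO5_ALOGP_MAX = 5.0
RO5_HBD_MAX = 5
RO5_HBA_MAX = 10


def lipinski_pass(profile: Optional[PhyschemProfile]) -> Optional[bool]:
    """Rule-of-Five drug-likeness gate.

    True iff MW < 500, AlogP < 5, H-bond donors < 5 and acceptors < 10
    (strict inequalities).  Returns ``None`` (ineligible) when any field
    is missing — a conservative reading that never auto-passes
    under-curated compounds.
    """
    if profile is None or not profile.complete:
        return None
    return (
        profile.mw < RO5_MW_MAX
        and profile.alogp < RO5_ALOGP_MAX
        and profile.hbd < RO5_HBD_MAX
        and profile.hba < RO5_HBA_MAX
    )


def admet_gate(scores: Optional[AdmetScores], threshold: float = 0.5) -> Optional[bool]:
    """Oral-absorption / brain-penetration gate.

    True iff both positive probabilities are >= threshold (inclusive at
    the boundary); ``None`` when scores are absent.
    """
    if scores is None:
        return None
    return scores.hia_prob >= threshold and scores.bbb_prob >= threshold


@dataclass(frozen=True)
class ScreenDecision:
    """Full audit trail for one compound through the four gates.

    Flags are ``True`` (pass), ``False`` (fail) or ``None`` (gate not
    computable for this compound).  ``retained`` requires all four to be
    ``True``.
    """

    compound_id: str
    step1_main_component: bool
    step2_ro5: Optional[bool]
    step3_admet: Optional[bool]
    step4_enrichment: Optional[bool]

    @property
    def retained(self) -> bool:
        return (
            self.step1_main_component
            and self.step2_ro5 is True
            and self.step3_admet is True
            and self.step4_enrichment is True
        )


@dataclass
class SimplificationReport:
    decisions: list[ScreenDecision]
    admet_threshold: float
    q_star: float

    @property
    def retained(self) -> set[str]:
        return {d.compound_id for d in self.decisions if d.retained}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": d.compound_id,
                    "main_component": d.step1_main_component,
                    "ro5": d.step2_ro5,
                    "admet": d.step3_admet,
                    "enrichment": d.step4_enrichment,
                    "retained": d.retained,
                }
                for d in self.decisions
            ]
        )


def four_step_screen(
    main_components: Iterable[str],
    compounds: Sequence[CompoundRecord],
    enrichment: Union[Sequence[EnrichmentRecord], Mapping[str, float]],
    admet_threshold: float = 0.5,
    q_star: float = 0.05,
) -> SimplificationReport:
    """Run all four gates over every compound and keep the full audit.

    ``enrichment`` is either the record list from the disease screen or
    a plain mapping compound_id -> q (for externally supplied q-values).
    Every gate is evaluated for every compound even after an earlier
    failure, so the report explains *why* each compound dropped out.
    Main components absent from the compound table are warned about and
    excluded.
    """
    if isinstance(enrichment, Mapping):
        qmap = dict(enrichment)
    else:
        qmap = {r.compound_id: r.q for r in enrichment}
    known_ids = {c.compound_id for c in compounds}
    main = set(main_components)
    missing_main = main - known_ids
    if missing_main:
        log.warning(
            "%d main component(s) absent from the compound table, excluded: %s",
            len(missing_main), sorted(missing_main)[:5],
        )
        main &= known_ids

    decisions = []
    for comp in compounds:
        q = qmap.get(comp.compound_id)
        decisions.append(
            ScreenDecision(
                compound_id=comp.compound_id,
                step1_main_component=comp.compound_id in main,
                step2_ro5=lipinski_pass(comp.physchem),
                step3_admet=admet_gate(comp.admet, admet_threshold),
                step4_enrichment=None if q is None else q < q_star,
            )
        )
    return SimplificationReport(decisions, admet_threshold, q_star)
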