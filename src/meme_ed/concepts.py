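"""The six EHR concept streams and their canonical order.

Every place a sequence of concepts appears (pseudo-note rendering, embedding
concatenation, attention positions) uses this fixed order.
"""

from __future__ import annotations

import enum


class ConceptKind(str, enum.Enum):
    """One of the six ED data domains embedded separately."""

    ARRIVAL = "arrival"      # demographics + means of arrival (stay metadata)
    TRIAGE = "triage"        # vitals + acuity + chief complaint at ED arrival
    MEDRECON = "medrecon"    # medication reconciliation (pre-existing meds)
    VITALS = "vitals"        # periodic vital-sign measurements during the stay
    PYXIS = "pyxis"          # medications dispensed during the ED stay
    DIAGNOSIS = "diagnosis"  # discharge diagnoses, ICD-9/10

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONCEPT_ORDER: tuple[ConceptKind, ...] = (
    ConceptKind.ARRIVAL,
    ConceptKind.TRIAGE,
    ConceptKind.MEDRECON,
    ConceptKind.VITALS,
    ConceptKind.PYXIS,
    ConceptKind.DIAGNOSIS,
)

N_CONCEPTS = len(CONCEPT_ORDER)


def concept_index(kind: ConceptKind) -> int:
    return CONCEPT_ORDER.index(ConceptKind(kind))
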