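"""Shared column layout for the patient-record table.

One row per trial participant; follow-up visits are stored wide
(one block of columns per assessment at 3, 6, 9 and 12 months after
the index surgery).  All downstream stages (valuation, outcome
construction, imputation, analysis) address columns through the
helpers defined here, so the layout is defined in exactly one place.
"""

from __future__ import annotations

#: Postoperative assessment months.
VISIT_MONTHS: tuple[int, ...] = (3, 6, 9, 12)

#: Day offset of each assessment relative to the index surgery (day 0).
VISIT_DAYS: dict[int, int] = {3: 91, 6: 183, 9: 274, 12: 365}

#: Delivery settings of the prehabilitation programme.
SETTINGS: tuple[str, ...] = (
    "mobile",
    "outpatient",
    "outpatient_transport",
    "part_inpatient",
    "inpatient",
)

#: Resource-use questionnaire items (one answer per item per visit,
#: 3-month recall window).  Maps item -> (cost category, integer-valued).
#: ``medication_uses`` is carried in the schema but never valued: no
#: standardised unit costs exist for medications.
RESOURCE_ITEMS: dict[str, tuple[str | None, bool]] = {
    "physician_visits": ("visits_physician", True),
    "therapist_visits": ("visits_therapist", True),
    "mobile_nursing_hours": ("mobile_nursing", False),
    "household_assistance_hours": ("household_assistance", False),
    "informal_care_hours": ("informal_care", False),
    "neighbour_help_hours": ("neighbour_help", False),
    "day_care_days": ("day_care", True),
    "short_term_care_days": ("short_term_care", True),
    "nursing_home_days": ("nursing_home", True),
    "medication_uses": (None, True),
    "rehabilitation_days": ("rehabilitation", True),
    "day_clinic_days": ("hospital_outpatient", True),
    "hospital_days": ("hospital_inpatient", True),
    "psychiatric_days": ("psychiatry", True),
    "auxiliary_aids_count": ("auxiliary_aids", True),
    "housing_adaptation_count": ("housing_adaptation", True),
}

#: Follow-up cost categories (rows of the cost-overview table), in
#: reporting order.
FOLLOWUP_CATEGORIES: tuple[str, ...] = (
    "hospital_inpatient",
    "hospital_outpatient",
    "psychiatry",
    "visits_physician",
    "visits_therapist",
    "mobile_nursing",
    "informal_care",
    "household_assistance",
    "neighbour_help",
    "day_care",
    "short_term_care",
    "nursing_home",
    "rehabilitation",
    "auxiliary_aids",
    "housing_adaptation",
)

#: Items feeding each category (inverse of RESOURCE_ITEMS).
CATEGORY_ITEMS: dict[str, tuple[str, ...]] = {
    cat: tuple(i for i, (c, _) in RESOURCE_ITEMS.items() if c == cat)
    for cat in FOLLOWUP_CATEGORIES
}


def ru_col(item: str, month: int) -> str:
    """Column name of a resource-use answer at a given visit."""
    return f"ru_{item}_{month}m"


def eq5d_col(month: int) -> str:
    """Column name of the EQ-5D-5L state at a given visit."""
    return f"eq5d_{month}m"


def cost_col(category: str, month: int) -> str:
    """Column name of a valued follow-up cost component."""
    return f"cost_{category}_{month}m"


def util_col(month: int) -> str:
    """Column name of the EQ-5D-5L utility at a given visit."""
    return f"util_{month}m"


def followup_cost_columns() -> list[str]:
    """All valued follow-up component columns in canonical order."""
    return [cost_col(c, t) for c in FOLLOWUP_CATEGORIES for t in VISIT_MONTHS]
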