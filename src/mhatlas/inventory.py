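"""Service inventory data model and inclusion-rule engine.

A *service* is the named organisation of care delivery (acute ward, day
hospital, community mental health centre, ...). Each service decomposes into
*basic stable inputs of care* (BSICs) — stable functional teams identified by
placement, target patients, common staff, administrative autonomy and
temporal stability — and each BSIC is classified by one principal main type
of care (MTC) plus optional additional codes.

The inclusion filter mirrors the comparative-mapping convention: publicly
funded care with universal access, serving adults (18+) with a psychiatric
disorder; specialised services for substance dependence, intellectual
disability, children/adolescents and criminal justice are excluded, as are
elderly-specific services without a mental-health remit; general (non
mental-health-specific) services qualify only when at least 20% of their
users have a mental disorder; specialised services located outside the study
area but serving its residents are kept.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .taxonomy import CodeRegistry, MTCCode, UnknownCodeError, branch_group

__all__ = [
    "GOVERNANCE_TYPES",
    "SECTORS",
    "TARGET_GROUP_TAGS",
    "STAFF_GROUPS",
    "STABILITY_CRITERIA",
    "Service",
    "BSIC",
    "InclusionDecision",
    "RuleConfig",
    "BsicRejectionError",
    "apply_inclusion_rules",
    "identify_bsic",
    "assign_codes",
    "validate_inventory",
    "InventoryReport",
]

GOVERNANCE_TYPES = ("public", "private_funded_public", "other")
SECTORS = ("health", "social", "education", "employment", "housing", "justice")
TARGET_GROUP_TAGS = (
    "adult_mh",
    "alcohol_drug",
    "intellectual_disability",
    "child_adolescent",
    "criminal_justice",
    "elderly_specific",
    "general",
)
STAFF_GROUPS = (
    "physicians",
    "psychologists",
    "nurses",
    "social_workers",
    "occupational_therapists",
    "other_workers",
)
STABILITY_CRITERIA = (
    "placement",
    "target_patients",
    "common_staff",
    "administrative_autonomy",
    "temporal_stability",
)
UTILISATION_FIELDS = ("admissions", "contacts", "bed_days", "users")

# Specialised target groups excluded from adult mental-health comparison.
_SPECIALISED_EXCLUDED = frozenset(
    {"alcohol_drug", "intellectual_disability", "child_adolescent", "criminal_justice"}
)


@dataclass
class Service:
    """One named service of the inventory."""

    id: str
    name: str = ""
    governance: str = "public"
    publicly_funded: bool = True
    universal_access: bool = True
    sector: str = "health"
    lon: float | None = None
    lat: float | None = None
    address: str = ""
    zoning_level: str = "none"  # H3 (hospital), H4 (MH centre), H5 (primary care), none
    catchment_id: str | None = None
    reference_year: int | None = None
    inside_study_area: bool = True
    target_group_tags: frozenset[str] = frozenset({"adult_mh"})
    pct_users_with_mental_disorder: float | None = None
    contacts_info: str = ""

    def __post_init__(self) -> None:
        self.target_group_tags = frozenset(self.target_group_tags)
        unknown = self.target_group_tags - set(TARGET_GROUP_TAGS)
        if unknown:
            raise ValueError(f"service {self.id}: unknown target group tags {sorted(unknown)}")
        if self.governance not in GOVERNANCE_TYPES:
            raise ValueError(f"service {self.id}: unknown governance {self.governance!r}")
        if self.sector not in SECTORS:
            raise ValueError(f"service {self.id}: unknown sector {self.sector!r}")
        if self.zoning_level not in ("H3", "H4", "H5", "none"):
            raise ValueError(f"service {self.id}: unknown zoning level {self.zoning_level!r}")
        p = self.pct_users_with_mental_disorder
        if p is not None and not (0.0 <= p <= 1.0):
            raise ValueError(f"service {self.id}: pct_users_with_mental_disorder {p} not in [0, 1]")
        if (self.lon is None) != (self.lat is None):
            raise ValueError(f"service {self.id}: lon/lat must both be set or both missing")
        if self.lon is not None and not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"service {self.id}: non-finite coordinates")


@dataclass
class BSIC:
    """A basic stable input of care within a service."""

    id: str
    service_id: str
    stability: dict[str, bool] = field(default_factory=dict)
    mtc_codes: list[str] = field(default_factory=list)  # first entry is the principal code
    beds: int = 0
    day_places: int = 0
    staff_fte: dict[str, float] = field(default_factory=dict)
    utilisation: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beds < 0 or self.day_places < 0:
            raise ValueError(f"BSIC {self.id}: beds/day_places must be >= 0")
        for group, fte in self.staff_fte.items():
            if group not in STAFF_GROUPS:
                raise ValueError(f"BSIC {self.id}: unknown staff group {group!r}")
            if fte < 0:
                raise ValueError(f"BSIC {self.id}: negative FTE for {group}")
        for k, v in self.utilisation.items():
            if k not in UTILISATION_FIELDS:
                raise ValueError(f"BSIC {self.id}: unknown utilisation field {k!r}")
            if v is not None and v < 0:
                raise ValueError(f"BSIC {self.id}: negative utilisation count {k}={v}")

    @property
    def principal_code(self) -> str | None:
        return self.mtc_codes[0] if self.mtc_codes else None

    @property
    def additional_codes(self) -> list[str]:
        return list(self.mtc_codes[1:])

    def total_fte(self) -> float:
        return float(sum(self.staff_fte.values()))


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.included and not self.reasons:
            raise ValueError("an excluded record must carry at least one reason")


@dataclass(frozen=True)
class RuleConfig:
    """Tunable parameters of the inclusion filter."""

    mh_user_threshold: float = 0.20  # minimum share of users with mental disorders
    reference_year: int | None = None  # when set, records from other years are excluded


class BsicRejectionError(ValueError):
    """A candidate unit fails one or more BSIC stability criteria
    (i.e. it is an activity or programme, not a stable functional team)."""

    def __init__(self, bsic_id: str, failed: Sequence[str]):
        self.bsic_id = bsic_id
        self.failed_criteria = tuple(failed)
        super().__init__(
            f"unit {bsic_id} is not a BSIC; failed stability criteria: {', '.join(failed)}"
        )


def apply_inclusion_rules(service: Service, config: RuleConfig | None = None) -> InclusionDecision:
    """Apply the comparative-mapping inclusion filter to one service record.

    Rules are evaluated in a fixed order but *all* failed rules are reported,
    so the decision is deterministic and independent of inventory order.
    A general service with no recorded share of mental-disorder users is a
    data error, not an exclusion.
    """
    config = config or RuleConfig()
    reasons: list[str] = []
    tags = service.target_group_tags

    if not service.publicly_funded:
        reasons.append("not_publicly_funded")
    if not service.universal_access:
        reasons.append("no_universal_access")

    if config.reference_year is not None and service.reference_year is not None:
        if service.reference_year != config.reference_year:
            reasons.append("outside_reference_year")

    if tags & _SPECIALISED_EXCLUDED and "adult_mh" not in tags:
        reasons.append("specialised_exclusion")

    # Elderly-specific services are excluded unless they have an explicit
    # mental-health remit (adult_mh tag).
    if "elderly_specific" in tags and "adult_mh" not in tags:
        reasons.append("elderly_specific_exclusion")

    if "general" in tags:
        p = service.pct_users_with_mental_disorder
        if p is None:
            raise ValueError(
                f"service {service.id}: general service requires "
                "pct_users_with_mental_disorder"
            )
        if p < config.mh_user_threshold:  # "at least 20%" -> inclusive boundary
            reasons.append("below_mh_user_threshold")

    # Specialised mental-health services outside the study area that serve its
    # residents are kept; outside general services are not compared.
    if not service.inside_study_area and ("general" in tags or "adult_mh" not in tags):
        reasons.append("outside_area_not_specialised")

    return InclusionDecision(included=not reasons, reasons=tuple(reasons))


def identify_bsic(candidate: BSIC) -> BSIC:
    """Accept a candidate unit as a BSIC iff all five stability criteria hold."""
    missing = [c for c in STABILITY_CRITERIA if c not in candidate.stability]
    if missing:
        raise ValueError(f"BSIC {candidate.id}: stability flags not populated: {missing}")
    failed = [c for c in STABILITY_CRITERIA if not candidate.stability[c]]
    if failed:
        raise BsicRejectionError(candidate.id, failed)
    return candidate


def assign_codes(
    bsic: BSIC, codes: Sequence[MTCCode | str], registry: CodeRegistry
) -> BSIC:
    """Attach MTC codes to a BSIC; the first code is the principal one.

    More than four codes is accepted but flagged with a warning — units
    needing more than four codes for a full description are rare.
    """
    if not codes:
        raise ValueError(f"BSIC {bsic.id}: at least one MTC code is required")
    canonical = [registry.get(str(c)).code for c in codes]
    if len(set(canonical)) != len(canonical):
        raise ValueError(f"BSIC {bsic.id}: duplicate MTC codes {canonical}")
    if len(canonical) > 4:
        warnings.warn(
            f"BSIC {bsic.id} described with {len(canonical)} MTC codes; "
            "units rarely need more than four",
            UserWarning,
            stacklevel=2,
        )
    return dataclasses.replace(bsic, mtc_codes=canonical)


@dataclass
class InventoryIssue:
    kind: str
    record_id: str
    message: str


@dataclass
class InventoryReport:
    issues: list[InventoryIssue]
    n_services: int
    n_included: int
    n_excluded: int
    exclusion_reasons: dict[str, int]
    n_bsics: int

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_inventory(
    services: Iterable[Service],
    bsics: Iterable[BSIC],
    registry: CodeRegistry,
    config: RuleConfig | None = None,
) -> InventoryReport:
    """Cross-check an inventory and summarise inclusion decisions (report-only)."""
    services = list(services)
    bsics = list(bsics)
    issues: list[InventoryIssue] = []

    service_ids = set()
    for s in services:
        if s.id in service_ids:
            issues.append(InventoryIssue("duplicate_service", s.id, "duplicate service id"))
        service_ids.add(s.id)
        if s.zoning_level != "none" and s.catchment_id is None:
            issues.append(
                InventoryIssue(
                    "missing_denominator",
                    s.id,
                    f"zoning level {s.zoning_level} declared but no catchment id",
                )
            )

    seen_bsics = set()
    for b in bsics:
        if b.id in seen_bsics:
            issues.append(InventoryIssue("duplicate_bsic", b.id, "duplicate BSIC id"))
        seen_bsics.add(b.id)
        if b.service_id not in service_ids:
            issues.append(
                InventoryIssue("orphan_bsic", b.id, f"unknown service_id {b.service_id!r}")
            )
        if not b.mtc_codes:
            issues.append(InventoryIssue("uncoded_bsic", b.id, "no MTC codes assigned"))
        else:
            for c in b.mtc_codes:
                try:
                    registry.get(c)
                except (UnknownCodeError, ValueError) as exc:
                    issues.append(InventoryIssue("unknown_code", b.id, str(exc)))
        if b.beds > 0 and b.principal_code and branch_group(b.principal_code) != "R":
            issues.append(
                InventoryIssue(
                    "beds_on_non_residential",
                    b.id,
                    f"beds reported on principal code {b.principal_code}",
                )
            )

    n_included = 0
    reasons: dict[str, int] = {}
    for s in services:
        decision = apply_inclusion_rules(s, config)
        if decision.included:
            n_included += 1
        else:
            for r in decision.reasons:
                reasons[r] = reasons.get(r, 0) + 1

    return InventoryReport(
        issues=issues,
        n_services=len(services),
        n_included=n_included,
        n_excluded=len(services) - n_included,
        exclusion_reasons=reasons,
        n_bsics=len(bsics),
    )
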