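"""Biologic identification from claims codes, and Charlson comorbidity scoring.

Biologic exposure is recorded in administrative claims through two routes:
self-injected products appear as pharmacy fills carrying an NDC, while
facility-infused products appear as medical claims carrying a drug-administration
HCPCS code. Vedolizumab, approved in 2014, had no product-specific permanent
HCPCS code during the study years and is identified by a rule-based algorithm
instead: a pharmacy claim with a vedolizumab NDC, a medical claim with the
unclassified-biologic code J3590 whose primary diagnosis is ulcerative colitis
(ICD-9-CM 556.xx) or Crohn's disease (555.xx), or a medical claim with C9026
or J3380.

The default code maps shipped with the package (``data/drug_codes.yaml``) are
documented reconstructions — standard J-codes plus representative labeled
NDCs — and are fully overrideable; pipeline correctness does not depend on
the specific lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

BIOLOGICS: tuple[str, ...] = (
    "adalimumab",
    "certolizumab",
    "infliximab",
    "natalizumab",
    "ustekinumab",
    "golimumab",
    "vedolizumab",
)

#: ICD-9-CM prefixes for the two disease cohorts.
UC_DX_PREFIX = "556"
CD_DX_PREFIX = "555"

#: Unclassified-biologic HCPCS code used by the vedolizumab rule.
VEDO_UNCLASSIFIED_HCPCS = "J3590"


@dataclass(frozen=True)
class DrugCodeMap:
    """Identification codes and dosing schedule for one biologic."""

    drug: str
    ndc_codes: frozenset[str]
    hcpcs_codes: frozenset[str]
    dosing_interval_days: int
    #: claim stream on which the synthetic generator emits this drug
    route: str = "medical"

    def __post_init__(self) -> None:
        if self.dosing_interval_days <= 0:
            raise ValueError(f"{self.drug}: dosing_interval_days must be > 0")
        if self.route not in ("pharmacy", "medical"):
            raise ValueError(f"{self.drug}: route must be 'pharmacy' or 'medical'")


@dataclass(frozen=True)
class CharlsonCategory:
    """One comorbidity category: ICD-9-CM prefixes and its integer weight."""

    name: str
    prefixes: tuple[str, ...]
    weight: int

    def __post_init__(self) -> None:
        if self.weight not in (1, 2, 3, 6):
            raise ValueError(f"{self.name}: weight must be one of 1, 2, 3, 6")


def _package_yaml(name: str):
    with resources.files("ibd_claims.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_drug_code_maps(path: str | Path | None = None) -> dict[str, DrugCodeMap]:
    """Load drug code maps from YAML (packaged defaults if *path* is None).

    Raises ``ValueError`` if any NDC or HCPCS code appears under two drugs.
    """
    raw = yaml.safe_load(Path(path).read_text()) if path else _package_yaml("drug_codes.yaml")
    maps: dict[str, DrugCodeMap] = {}
    for drug, entry in raw.items():
        maps[drug] = DrugCodeMap(
            drug=drug,
            ndc_codes=frozenset(str(c) for c in entry.get("ndc", [])),
            hcpcs_codes=frozenset(str(c) for c in entry.get("hcpcs", [])),
            dosing_interval_days=int(entry["dosing_interval_days"]),
            route=entry.get("route", "medical"),
        )
    seen: dict[str, str] = {}
    for m in maps.values():
        for code in m.ndc_codes | m.hcpcs_codes:
            if code in seen and seen[code] != m.drug:
                raise ValueError(f"code {code!r} mapped to both {seen[code]} and {m.drug}")
            seen[code] = m.drug
    return maps


def load_charlson_map(path: str | Path | None = None) -> tuple[CharlsonCategory, ...]:
    raw = yaml.safe_load(Path(path).read_text()) if path else _package_yaml("charlson.yaml")
    return tuple(
        CharlsonCategory(name=name, prefixes=tuple(str(p) for p in e["prefixes"]), weight=int(e["weight"]))
        for name, e in raw.items()
    )


def medication_hcpcs(maps: Mapping[str, DrugCodeMap]) -> frozenset[str]:
    """All drug-administration HCPCS codes, used to route claim dollars to pharmacy cost."""
    codes: set[str] = set()
    for m in maps.values():
        codes |= m.hcpcs_codes
    codes.add(VEDO_UNCLASSIFIED_HCPCS)
    return frozenset(codes)


def normalize_ndc(code: object) -> str | None:
    """Zero-pad an NDC to 11 digits; return None for malformed codes."""
    s = str(code).replace("-", "").strip()
    if not s.isdigit() or len(s) > 11:
        return None
    return s.zfill(11)


def _is_ibd_primary(dx1: object) -> bool:
    s = "" if dx1 is None or (isinstance(dx1, float) and pd.isna(dx1)) else str(dx1)
    return s.startswith(UC_DX_PREFIX) or s.startswith(CD_DX_PREFIX)


def detect_vedolizumab(
    claim: Mapping[str, object],
    kind: str,
    maps: Mapping[str, DrugCodeMap],
) -> dict | None:
    """Apply the rule-based vedolizumab algorithm to a single claim.

    Parameters
    ----------
    claim
        Mapping with the claim's fields (pharmacy: ``fill_date``, ``ndc``,
        ``days_supply``; medical: ``service_start``, ``hcpcs``, ``dx1``).
    kind
        ``"pharmacy"`` or ``"medical"``.

    Returns an event dict (person_id, event_date, drug, route, days_supply)
    or None when no rule fires.
    """
    vmap = maps["vedolizumab"]
    if kind == "pharmacy":
        ndc = normalize_ndc(claim.get("ndc"))
        if ndc is not None and ndc in vmap.ndc_codes:
            return {
                "person_id": claim["person_id"],
                "event_date": claim["fill_date"],
                "drug": "vedolizumab",
                "route": "NDC",
                "days_supply": int(claim.get("days_supply") or 0),
            }
        return None
    hcpcs = claim.get("hcpcs")
    hcpcs = "" if hcpcs is None or (isinstance(hcpcs, float) and pd.isna(hcpcs)) else str(hcpcs)
    fires = hcpcs in vmap.hcpcs_codes or (
        hcpcs == VEDO_UNCLASSIFIED_HCPCS and _is_ibd_primary(claim.get("dx1"))
    )
    if fires:
        return {
            "person_id": claim["person_id"],
            "event_date": claim["service_start"],
            "drug": "vedolizumab",
            "route": "vedolizumab-algorithm",
            "days_supply": 0,
        }
    return None


_EVENT_COLUMNS = ["person_id", "event_date", "drug", "route", "days_supply"]


def classify_claims(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    maps: Mapping[str, DrugCodeMap],
) -> pd.DataFrame:
    """Derive dated biologic exposures from the two claim streams.

    One event is produced per matching claim line; non-matching claims
    produce none. Vedolizumab is identified exclusively through its
    rule-based algorithm (NDC fill, J3590 with a primary UC/CD diagnosis,
    or C9026/J3380); the other six drugs through direct NDC/HCPCS lookup.
    Output is sorted by (person_id, event_date, drug) so the result is
    independent of input row order.
    """
    ndc_to_drug: dict[str, str] = {}
    hcpcs_to_drug: dict[str, str] = {}
    for m in maps.values():
        if m.drug == "vedolizumab":
            continue  # handled only via the algorithm
        for c in m.ndc_codes:
            ndc_to_drug[c] = m.drug
        for c in m.hcpcs_codes:
            hcpcs_to_drug[c] = m.drug

    frames: list[pd.DataFrame] = []

    if len(pharmacy):
        ph = pharmacy.copy()
        ph["_ndc"] = ph["ndc"].map(normalize_ndc)
        bad = ph["_ndc"].isna() & ph["ndc"].notna()
        if bad.any():
            log.warning("skipping %d pharmacy claims with malformed NDC", int(bad.sum()))
        ph["drug"] = ph["_ndc"].map(ndc_to_drug)
        hit = ph[ph["drug"].notna()]
        if len(hit):
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": hit["person_id"],
                        "event_date": hit["fill_date"],
                        "drug": hit["drug"],
                        "route": "NDC",
                        "days_supply": hit["days_supply"].fillna(0).astype(int),
                    }
                )
            )
        vmap = maps["vedolizumab"]
        vhit = ph[ph["_ndc"].isin(vmap.ndc_codes)]
        if len(vhit):
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": vhit["person_id"],
                        "event_date": vhit["fill_date"],
                        "drug": "vedolizumab",
                        "route": "NDC",
                        "days_supply": vhit["days_supply"].fillna(0).astype(int),
                    }
                )
            )

    if len(medical):
        md = medical.copy()
        hc = md["hcpcs"].astype("string").fillna("")
        md["drug"] = hc.map(hcpcs_to_drug)
        hit = md[md["drug"].notna()]
        if len(hit):
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": hit["person_id"],
                        "event_date": hit["service_start"],
                        "drug": hit["drug"],
                        "route": "HCPCS",
                        "days_supply": 0,
                    }
                )
            )
        vmap = maps["vedolizumab"]
        dx1 = md["dx1"].astype("string").fillna("")
        vmask = hc.isin(vmap.hcpcs_codes) | (
            (hc == VEDO_UNCLASSIFIED_HCPCS)
            & (dx1.str.startswith(UC_DX_PREFIX) | dx1.str.startswith(CD_DX_PREFIX))
        )
        vhit = md[vmask]
        if len(vhit):
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": vhit["person_id"],
                        "event_date": vhit["service_start"],
                        "drug": "vedolizumab",
                        "route": "vedolizumab-algorithm",
                        "days_supply": 0,
                    }
                )
            )

    if not frames:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    events = pd.concat(frames, ignore_index=True)[_EVENT_COLUMNS]
    events["event_date"] = pd.to_datetime(events["event_date"])
    return events.sort_values(["person_id", "event_date", "drug"], kind="mergesort").reset_index(
        drop=True
    )


def charlson_score(
    dx_codes: Iterable[object],
    cmap: tuple[CharlsonCategory, ...] | None = None,
) -> int:
    """Charlson comorbidity score from baseline diagnosis codes.

    Each category contributes its weight once if any observed code starts
    with one of its prefixes, regardless of how many claims carry it.
    No age adjustment is applied.
    """
    if cmap is None:
        cmap = load_charlson_map()
    codes = [str(c) for c in dx_codes if c is not None and not (isinstance(c, float) and pd.isna(c))]
    score = 0
    for cat in cmap:
        if any(code.startswith(p) for code in codes for p in cat.prefixes):
            score += cat.weight
    return score
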