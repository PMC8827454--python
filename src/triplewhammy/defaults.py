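"""Default configuration lists.

The analysis is driven by membership lists rather than by a drug or event
dictionary: which Preferred Terms (PTs) count as acute kidney injury (AKI),
which drug names belong to each Triple Whammy (TW) class — renin-angiotensin
system inhibitors (RASIs), diuretics, NSAIDs — which names are aspirin
(excluded from the NSAID class because it is typically given at antiplatelet
doses), and which non-TW drugs are treated as independent AKI-risk covariates.

The defaults below are compact generic-name lists sufficient for synthetic
data and for testing; production use against a real spontaneous-report
release should supply complete lists (including brand names) via YAML/JSON —
see :func:`load_lists_yaml`.
"""

from __future__ import annotations

import unicodedata
from pathlib import Path
from typing import Iterable

import yaml

# PTs from the MedDRA standardized query for acute renal failure (subset of
# generic-name level terms; extend via config for a specific MedDRA version).
DEFAULT_AKI_PTS: frozenset[str] = frozenset(
    {
        "Acute kidney injury",
        "Renal failure",
        "Renal failure acute",
        "Renal impairment",
        "Anuria",
        "Oliguria",
        "Azotaemia",
        "Nephropathy toxic",
        "Renal tubular necrosis",
        "Prerenal failure",
    }
)

# Decoy PTs used for non-AKI reactions in synthetic data.
DECOY_PTS: tuple[str, ...] = (
    "Nausea",
    "Rash",
    "Hepatic function abnormal",
    "Interstitial lung disease",
    "Dizziness",
    "Diarrhoea",
    "Pyrexia",
    "Thrombocytopenia",
)

DEFAULT_RASI: frozenset[str] = frozenset(
    {
        "enalapril",
        "lisinopril",
        "imidapril",
        "perindopril",
        "temocapril",
        "candesartan",
        "losartan",
        "valsartan",
        "telmisartan",
        "olmesartan",
        "irbesartan",
        "azilsartan",
        "aliskiren",
    }
)

DEFAULT_DIURETIC: frozenset[str] = frozenset(
    {
        "furosemide",
        "azosemide",
        "torasemide",
        "hydrochlorothiazide",
        "trichlormethiazide",
        "indapamide",
        "spironolactone",
        "eplerenone",
        "triamterene",
        "tolvaptan",
    }
)

DEFAULT_NSAID: frozenset[str] = frozenset(
    {
        "loxoprofen",
        "ibuprofen",
        "diclofenac",
        "naproxen",
        "ketoprofen",
        "indomethacin",
        "meloxicam",
        "etodolac",
        "celecoxib",
        "flurbiprofen",
        "mefenamic acid",
        "piroxicam",
    }
)

DEFAULT_ASPIRIN: frozenset[str] = frozenset({"aspirin", "acetylsalicylic acid"})

# Non-TW drugs treated as AKI-risk covariates, grouped for reporting.
DEFAULT_AKI_RISK_GROUPS: dict[str, frozenset[str]] = {
    "Valaciclovir": frozenset({"valaciclovir", "valaciclovir hydrochloride"}),
    "Eldecalcitol": frozenset({"eldecalcitol"}),
    "Edaravone": frozenset({"edaravone"}),
    "Aciclovir": frozenset({"aciclovir"}),
    "Tazobactam-Piperacillin": frozenset(
        {"tazobactam-piperacillin", "tazobactam-piperacillin hydrate"}
    ),
    "Vancomycin": frozenset({"vancomycin", "vancomycin hydrochloride"}),
    "Famotidine": frozenset({"famotidine"}),
    "Levofloxacin": frozenset({"levofloxacin"}),
    "Proton pump inhibitors": frozenset(
        {
            "esomeprazole",
            "lansoprazole",
            "omeprazole",
            "pantoprazole",
            "rabeprazole",
            "vonoprazan",
        }
    ),
    "Aminoglycosides": frozenset(
        {
            "amikacin",
            "arbekacin",
            "bekanamycin",
            "dibekacin",
            "fradiomycin",
            "gentamicin",
            "isepamicin",
            "kanamycin",
            "micronomicin",
            "netilmicin",
            "paromomycin",
            "ribostamycin",
            "streptomycin",
            "tobramycin",
        }
    ),
}

DEFAULT_AKI_RISK: frozenset[str] = frozenset(
    name for group in DEFAULT_AKI_RISK_GROUPS.values() for name in group
)

# Keywords in a dosage-form / route field that indicate topical administration.
# Anything non-empty that does not match is treated as systemic.
DEFAULT_TOPICAL_KEYWORDS: tuple[str, ...] = (
    "topical",
    "ointment",
    "cream",
    "gel",
    "patch",
    "plaster",
    "tape",
    "poultice",
    "cataplasm",
    "lotion",
    "eye drop",
    "external",
)

# Filler drugs for synthetic cases outside the TW classes.
FILLER_DRUGS: tuple[str, ...] = (
    "acetaminophen",
    "amlodipine",
    "metformin",
    "atorvastatin",
    "warfarin",
)

OUTCOME_CATEGORIES: tuple[str, ...] = (
    "Recovered",
    "Remission",
    "Unrecovered",
    "Death",
    "With sequelae",
    "unknown",
)


def normalize_name(name: str) -> str:
    """Normalize a drug name or PT for exact matching.

    Unicode-width unification (NFKC), trim, case-fold. No fuzzy matching:
    classification must stay deterministic and auditable.
    """
    return unicodedata.normalize("NFKC", name).strip().casefold()


def normalize_set(names: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_name(n) for n in names)


def load_lists_yaml(path: str | Path) -> dict[str, frozenset[str]]:
    """Load membership lists from a YAML file.

    Expected top-level keys (each a list of strings): ``aki_pts``, ``rasi``,
    ``diuretic``, ``nsaid``, ``aspirin``, ``aki_risk``. Missing keys fall back
    to the package defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, frozenset[str]] = {}
    fallbacks = {
        "aki_pts": DEFAULT_AKI_PTS,
        "rasi": DEFAULT_RASI,
        "diuretic": DEFAULT_DIURETIC,
        "nsaid": DEFAULT_NSAID,
        "aspirin": DEFAULT_ASPIRIN,
        "aki_risk": DEFAULT_AKI_RISK,
    }
    for key, fallback in fallbacks.items():
        values = raw.get(key)
        out[key] = frozenset(values) if values is not None else frozenset(fallback)
    return out
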