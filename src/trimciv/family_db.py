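"""TRIM family registry and the curated TRIM-target pair database.

The registry is the source of truth for subfamily membership (CI..CXI plus
an uncategorised UC group); :func:`classify_subfamily` validates a
subfamily call from domain architecture, or supplies one when the registry
omits it.  Class labels for supervised learning are assigned per pair:
TRUE when the TRIM belongs to the CIV subfamily, FALSE otherwise.
Uncategorised members that nonetheless carry a PRY-SPRY domain (e.g.
TRIM14-like entries) are excluded from both classes rather than labelled
FALSE, so they cannot contaminate either side of the decision boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Subfamily call constants.
CIV = "CIV"
NON_CIV = "NON_CIV"
EXCLUDED = "EXCLUDED"

#: Pair label constants (the supervised classes).
TRUE = "TRUE"
FALSE = "FALSE"
UNLABELED = "UNLABELED"

#: Closed domain vocabulary, canonical spellings.  Matching is
#: case-insensitive and ignores ``-``, ``_``, ``.`` and whitespace, so
#: "PRY-SPRY", "pryspry" and "B30.2" all resolve to PRYSPRY.
DOMAIN_VOCAB = frozenset(
    {
        "RING",
        "BBOX1",
        "BBOX2",
        "CC",
        "PRYSPRY",
        "COS",
        "FN3",
        "PHD",
        "BROMO",
        "NHL",
        "MATH",
        "ARF",
        "FIL",
        "TM",
    }
)

_ALIASES = {
    "B302": "PRYSPRY",
    "SPRY": "PRYSPRY",
    "B1": "BBOX1",
    "B2": "BBOX2",
    "COILEDCOIL": "CC",
}

#: Subfamily codes accepted in registry files.
SUBFAMILIES = tuple(
    ["CI", "CII", "CIII", "CIV", "CV", "CVI", "CVII", "CVIII", "CIX", "CX", "CXI", "UC"]
)

_TRIPARTITE_NTERM = {"RING", "BBOX1", "BBOX2"}


class DomainVocabularyError(ValueError):
    """An unrecognised domain token was encountered."""


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RegistryLookupError(KeyError):
    """A pair references a TRIM absent from the registry."""


def normalize_domain(token: str) -> str:
    """Resolve one domain token to its canonical vocabulary spelling."""
    canon = "".join(ch for ch in token.upper() if ch.isalnum())
    canon = _ALIASES.get(canon, canon)
    if canon not in DOMAIN_VOCAB:
        raise DomainVocabularyError(f"unknown domain name: {token!r}")
    return canon


@dataclass
class TrimEntry:
    """One TRIM family member.

    Parameters
    ----------
    name
        Gene symbol, unique within a registry.
    subfamily
        One of CI..CXI or UC; empty string if unknown (then
        :func:`classify_subfamily` is used as a fallback).
    domains
        Domain names in N- to C-terminal order.
    """

    name: str
    subfamily: str
    domains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains = [normalize_domain(d) for d in self.domains]
        if self.subfamily and self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r} for {self.name}")


@dataclass
class TrimTargetPair:
    """A curated or candidate (TRIM, target) pair."""

    trim: str
    target: str
    label: str = UNLABELED
    source: str = ""


def classify_subfamily(domains: list[str], registry_subfamily: str | None = None) -> str:
    """Call CIV / NON_CIV / EXCLUDED from domain architecture.

    A member is CIV when its C-terminal-most recognised domain is PRY-SPRY
    and it carries the tripartite core (a RING finger and/or B-box, plus a
    coiled-coil).  Members annotated UC in the registry that carry a
    PRY-SPRY are EXCLUDED: their functional classification is unresolved
    and keeping them in either class would blur the CIV boundary.

    Raises
    ------
    DomainVocabularyError
        If any domain token is not in the controlled vocabulary.
    ValueError
        If ``domains`` is empty.
    """
    if not domains:
        raise ValueError("domain list must be non-empty")
    canon = [normalize_domain(d) for d in domains]
    has_pryspry_cterm = canon[-1] == "PRYSPRY"
    if registry_subfamily == "UC":
        return EXCLUDED if "PRYSPRY" in canon else NON_CIV
    has_core = bool(_TRIPARTITE_NTERM.intersection(canon)) and "CC" in canon
    if has_pryspry_cterm and has_core:
        return CIV
    return NON_CIV


def effective_class(entry: TrimEntry) -> str:
    """CIV / NON_CIV / EXCLUDED for a registry entry.

    The registry subfamily is authoritative; domain architecture is only
    consulted when the subfamily field is blank.
    """
    if entry.subfamily == "CIV":
        return CIV
    if entry.subfamily == "UC":
        return EXCLUDED if "PRYSPRY" in entry.domains else NON_CIV
    if entry.subfamily:
        return NON_CIV
    return classify_subfamily(entry.domains)


def load_registry(path) -> list[TrimEntry]:
    """Read a registry TSV with columns ``name``, ``subfamily``, ``domains``.

    ``domains`` is comma-joined, N- to C-terminal order.  Duplicate names
    are collapsed to the first occurrence with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("name", "subfamily", "domains"):
        if col not in df.columns:
            raise SchemaError(f"registry file missing required column {col!r}")
    if df.empty:
        logger.warning("registry file %s has a header but no rows", path)
        return []
    dups = df["name"].duplicated()
    if dups.any():
        logger.warning("collapsing %d duplicate registry rows", int(dups.sum()))
        df = df[~dups]
    return [
        TrimEntry(r["name"], r["subfamily"], [d for d in r["domains"].split(",") if d])
        for _, r in df.iterrows()
    ]


def write_registry(entries: list[TrimEntry], path) -> None:
    df = pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "subfamily": [e.subfamily for e in entries],
            "domains": [",".join(e.domains) for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_pairs(path) -> list[TrimTargetPair]:
    """Read a pair TSV with columns ``trim``, ``target``, ``source``.

    An optional ``label`` column is honoured.  Duplicate (trim, target)
    rows collapse to the first occurrence with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("trim", "target"):
        if col not in df.columns:
            raise SchemaError(f"pair file missing required column {col!r}")
    if df.empty:
        logger.warning("pair file %s has a header but no rows", path)
        return []
    if (df["trim"] == "").any() or (df["target"] == "").any():
        raise SchemaError("pair file contains empty gene symbols")
    dups = df.duplicated(subset=["trim", "target"])
    if dups.any():
        logger.warning("collapsing %d duplicate (trim, target) rows", int(dups.sum()))
        df = df[~dups]
    has_label = "label" in df.columns
    has_source = "source" in df.columns
    return [
        TrimTargetPair(
            r["trim"],
            r["target"],
            r["label"] if has_label and r.get("label") else UNLABELED,
            r["source"] if has_source else "",
        )
        for _, r in df.iterrows()
    ]


def write_pairs(pairs: list[TrimTargetPair], path) -> None:
    df = pd.DataFrame(
        {
            "trim": [p.trim for p in pairs],
            "target": [p.target for p in pairs],
            "label": [p.label for p in pairs],
            "source": [p.source for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def assign_labels(
    pairs: list[TrimTargetPair], registry: list[TrimEntry]
) -> list[TrimTargetPair]:
    """Label pairs TRUE (CIV TRIM) / FALSE (other subfamily).

    Pairs whose TRIM is EXCLUDED (uncategorised with a PRY-SPRY) are
    dropped; the removal count is logged.  Idempotent: relabelling labelled
    pairs yields the same labels.

    Raises
    ------
    RegistryLookupError
        If any pair references a TRIM not present in the registry; the
        message lists every unmatched name.
    """
    by_name = {e.name: e for e in registry}
    missing = sorted({p.trim for p in pairs} - set(by_name))
    if missing:
        raise RegistryLookupError(f"TRIMs absent from registry: {', '.join(missing)}")
    out: list[TrimTargetPair] = []
    n_dropped = 0
    for p in pairs:
        cls = effective_class(by_name[p.trim])
        if cls == EXCLUDED:
            n_dropped += 1
            continue
        out.append(TrimTargetPair(p.trim, p.target, TRUE if cls == CIV else FALSE, p.source))
    if n_dropped:
        logger.info("dropped %d pairs of excluded (UC + PRY-SPRY) members", n_dropped)
    return out
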