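"""Site curation: entry/site-level filtering and oxidation-state assignment.

The filtering pipeline turns raw contact lists into fit-ready sites:

* entry-level rejection (disorder, high R factor, metal-carbon bonds);
* criterion (i): first-coordination-sphere trimming via the distance-cutoff
  transformation of the 5%-contribution rule, evaluated with literature
  reference parameters;
* criterion (ii): only N, O, F, S, Cl, Br ligands allowed;
* criterion (iii): at least two first-sphere ligands;
* criterion (iv): bond-valence sum inside (0, 2S), applied with literature
  parameters before fitting and re-applied with current parameters between
  optimizer restarts (see :mod:`bvfit.fitting`).

Oxidation states are assigned by a three-part cascade: explicit markers in
the compound name, then ligand-template charge balance, then a pluggable
mixed-metal hook (default: unassigned).  Bond-valence sums are never used
in the assignment, to keep it independent of the quantity being fitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import (
    BindingSite,
    ParameterSet,
    bvs,
    cutoff_distance,
)
from .errors import ConfigError, MissingParameterError, NoReferenceParameterError
from .reference import brese_okeeffe_params

ALLOWED_LIGANDS = frozenset({"N", "O", "F", "S", "Cl", "Br"})


@dataclass
class FilterConfig:
    """Thresholds of the curation pipeline."""

    max_r_factor: float = 0.075
    contribution_fraction: float = 0.05
    allowed_ligands: frozenset = ALLOWED_LIGANDS
    min_ligands: int = 2
    bvs_window_multiplier: float = 2.0
    contact_radius: float = 4.0
    reference_params: ParameterSet = field(default_factory=brese_okeeffe_params)

    def __post_init__(self):
        self.allowed_ligands = frozenset(self.allowed_ligands)
        if not (0 < self.contribution_fraction < 1):
            raise ConfigError("contribution_fraction must be in (0, 1)")
        if self.min_ligands < 2:
            raise ConfigError("min_ligands must be >= 2")
        if not (0 < self.max_r_factor < 1):
            raise ConfigError("max_r_factor must be in (0, 1) (a fraction)")
        if self.bvs_window_multiplier <= 0:
            raise ConfigError("bvs_window_multiplier must be positive")


@dataclass
class LedgerRecord:
    entry_id: str
    site_id: str
    stage: str  # "entry", "i", "ii", "iii", "iv", "oxidation", "kept"
    reason: str
    prune_pass: Optional[int] = None


class FilterLedger:
    """Audit trail: every input site appears exactly once as kept/rejected,
    plus any later pruning events from the fit loop."""

    def __init__(self):
        self.records: List[LedgerRecord] = []

    def add(self, site: BindingSite, stage: str, reason: str, prune_pass=None):
        self.records.append(
            LedgerRecord(site.entry_id, site.site_id, stage, reason, prune_pass)
        )

    def kept(self) -> List[LedgerRecord]:
        return [r for r in self.records if r.stage == "kept"]

    def rejected(self) -> List[LedgerRecord]:
        return [r for r in self.records if r.stage != "kept"]

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.stage] = out.get(r.stage, 0) + 1
        return out

    def __len__(self):
        return len(self.records)

    def to_rows(self) -> List[Dict[str, object]]:
        return [
            {
                "entry_id": r.entry_id,
                "site_id": r.site_id,
                "stage": r.stage,
                "reason": r.reason,
                "prune_pass": "" if r.prune_pass is None else r.prune_pass,
            }
            for r in self.records
        ]


def entry_filter(site: BindingSite, config: FilterConfig) -> Tuple[bool, Optional[str]]:
    """Entry-level screen: disorder, R factor, metal-carbon bonds.

    Returns ``(keep, reason)``; ``reason`` is None when kept.  A missing
    R factor is rejected conservatively.
    """
    if site.disordered:
        return False, "disorder"
    if site.r_factor is None:
        return False, "missing-metadata"
    if site.r_factor > config.max_r_factor:
        return False, "R-factor"
    if site.has_metal_carbon_bond:
        return False, "metal-carbon-bond"
    return True, None


def first_sphere(site: BindingSite, config: FilterConfig) -> BindingSite:
    """Criterion (i): trim contacts outside the first coordination sphere.

    Implemented as the closed-form distance cutoff of the 5% rule,
    evaluated per contact with the literature reference R0 for that
    ligand element -- a single pass that neither reorders nor alters the
    surviving contacts.
    """
    s = site.require_oxidation()
    ref = config.reference_params
    kept = []
    for contact in site.contacts:
        try:
            key = ref.resolve(site.metal_element, s, contact.ligand_element)
        except MissingParameterError:
            raise NoReferenceParameterError(
                f"no reference parameter for "
                f"{site.metal_element}({s})-{contact.ligand_element}"
            ) from None
        cutoff = cutoff_distance(
            ref.entries[key].r0, s, ref.b, config.contribution_fraction
        )
        if contact.distance <= cutoff:
            kept.append(contact)
    return site.with_contacts(kept)


def site_filter(
    site: BindingSite, config: FilterConfig, params: ParameterSet
) -> Tuple[bool, Optional[str]]:
    """Criteria (ii)-(iv) on a first-sphere-trimmed, oxidation-assigned site."""
    bad = [e for e in site.ligand_elements() if e not in config.allowed_ligands]
    if bad:
        return False, "ligand-element"
    if len(site.contacts) < config.min_ligands:
        return False, "min-ligands"
    s = site.require_oxidation()
    v = bvs(site, params)
    if not (0 < v < config.bvs_window_multiplier * s):
        return False, "bvs-window"
    return True, None


# ---------------------------------------------------------------------------
# Oxidation-state assignment
# ---------------------------------------------------------------------------

_METAL_NAMES = {
    "Fe": ["iron", "ferrate"],
    "Na": ["sodium"],
    "Mg": ["magnesium"],
    "K": ["potassium"],
    "Ca": ["calcium"],
    "Zn": ["zinc"],
    "Cu": ["copper", "cuprate"],
    "Mn": ["manganese", "manganate"],
    "Co": ["cobalt", "cobaltate"],
    "Ni": ["nickel", "nickelate"],
}

_ROMAN = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4,
    "v": 5, "vi": 6, "vii": 7, "viii": 8,
}

# "ferrous chloride" -> Fe(II); "ferric citrate" -> Fe(III).
_KEYWORD_STATES = {"Fe": {"ferrous": 2, "ferric": 3}}


def parse_oxidation_from_name(
    compound_name: str, metal_element: str
) -> Optional[int]:
    """Part (i) of the assignment cascade: read the state off the name.

    Detects roman numerals bound to the metal's name or symbol, e.g.
    "iron(II)", "di-iron(iii)", "Fe(II)", and the ferrous/ferric keywords.
    Returns None when no marker is found or when conflicting states for
    the same metal appear (mixed-valence names are not "clear and
    unambiguous").
    """
    if not compound_name:
        return None
    name = compound_name.lower()
    stems = list(_METAL_NAMES.get(metal_element, []))
    stems.append(metal_element.lower())
    found = set()
    roman_alt = "|".join(sorted(_ROMAN, key=len, reverse=True))
    for stem in stems:
        pattern = rf"\b[\w-]*{re.escape(stem)}\s*\(\s*({roman_alt})\s*\)"
        for match in re.finditer(pattern, name):
            found.add(_ROMAN[match.group(1)])
    for keyword, state in _KEYWORD_STATES.get(metal_element, {}).items():
        if re.search(rf"\b{keyword}\b", name):
            found.add(state)
    if len(found) == 1:
        return found.pop()
    return None  # absent, or conflicting (mixed-valence) markers


def assign_by_ligand_templates(
    site: BindingSite,
    template_charges: Sequence[Optional[int]] | Mapping[str, int],
    complex_charge: int,
    ligand_groups: Optional[Sequence[str]] = None,
) -> Optional[int]:
    """Part (ii): oxidation state by charge balance over ligand templates.

        S = complex_charge - sum(template charges of coordinated ligands)

    ``template_charges`` is either the per-ligand-group charge list itself
    (None marks an unmatched group) or a template table mapping group name
    to charge, in which case ``ligand_groups`` names the coordinated
    groups.  Which atoms constitute a donor group is the caller's problem;
    only the balance is computed here.  Returns None when any group is
    unmatched or the balance falls outside the plausible 1..8 range.
    """
    if ligand_groups is not None:
        if not isinstance(template_charges, Mapping):
            raise ConfigError(
                "ligand_groups requires template_charges to be a mapping"
            )
        charges = [template_charges.get(g.lower()) for g in ligand_groups]
    else:
        if isinstance(template_charges, Mapping):
            raise ConfigError(
                "a template_charges mapping requires explicit ligand_groups"
            )
        charges = list(template_charges)
    if any(c is None for c in charges):
        return None
    s = complex_charge - sum(charges)  # type: ignore[arg-type]
    if s not in range(1, 9):
        return None
    return s


#: Demonstration ligand-template table: donor-group name -> formal charge.
#: A stand-in for a full template catalog; the interface is pluggable.
DEMO_LIGAND_TEMPLATES: Dict[str, int] = {
    "aqua": 0, "water": 0, "ammine": 0, "ammonia": 0,
    "pyridine": 0, "imidazole": 0, "bipyridine": 0, "phenanthroline": 0,
    "triazole": 0, "thioether": 0, "nitrile": 0,
    "fluoride": -1, "chloride": -1, "bromide": -1,
    "hydroxide": -1, "hydroxo": -1, "thiolate": -1, "phenolate": -1,
    "carboxylate": -1, "acetate": -1, "nitrate": -1, "thiocyanate": -1,
    "oxo": -2, "sulfate": -2, "carbonate": -2, "oxalate": -2,
    "porphyrin": -2,
}

MixedMetalHook = Callable[[BindingSite], Optional[int]]


def assign_oxidation(
    site: BindingSite,
    compound_name: Optional[str] = None,
    template_charges: Optional[Sequence[Optional[int]] | Mapping[str, int]] = None,
    complex_charge: Optional[int] = None,
    ligand_groups: Optional[Sequence[str]] = None,
    mixed_metal_hook: Optional[MixedMetalHook] = None,
) -> Optional[int]:
    """Three-part assignment cascade.

    (i) an unambiguous marker in the compound name wins; (ii) otherwise
    ligand-template charge balance; (iii) otherwise a pluggable
    mixed-metal-statistics hook, which defaults to returning None
    (unassigned).  An unassigned site is excluded downstream.
    """
    name = site.compound_name if compound_name is None else compound_name
    state = parse_oxidation_from_name(name, site.metal_element)
    if state is not None:
        return state
    if template_charges is not None and complex_charge is not None:
        state = assign_by_ligand_templates(
            site, template_charges, complex_charge, ligand_groups
        )
        if state is not None:
            return state
    if mixed_metal_hook is not None:
        return mixed_metal_hook(site)
    return None


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def curate_sites(
    sites: Iterable[BindingSite],
    config: Optional[FilterConfig] = None,
    mixed_metal_hook: Optional[MixedMetalHook] = None,
) -> Tuple[List[BindingSite], FilterLedger]:
    """Run the full curation pipeline over a population.

    Order: entry filter -> oxidation assignment (name cascade) ->
    criterion (i) first-sphere trim -> criteria (ii)-(iv) with literature
    parameters.  Criterion (iv) is re-applied with current parameters
    inside the fit loop.  Returns the kept sites (trimmed, oxidation
    assigned) and a ledger partitioning the input.
    """
    config = config or FilterConfig()
    ledger = FilterLedger()
    kept: List[BindingSite] = []
    for site in sites:
        ok, reason = entry_filter(site, config)
        if not ok:
            ledger.add(site, "entry", reason)
            continue
        if site.oxidation_state is None:
            state = assign_oxidation(site, mixed_metal_hook=mixed_metal_hook)
            if state is None:
                ledger.add(site, "oxidation", "unassigned")
                continue
            site = replace(site, oxidation_state=state, contacts=list(site.contacts))
        try:
            trimmed = first_sphere(site, config)
        except NoReferenceParameterError as exc:
            ledger.add(site, "i", f"no-reference-parameter: {exc}")
            continue
        ok, reason = site_filter(trimmed, config, config.reference_params)
        if not ok:
            stage = {"ligand-element": "ii", "min-ligands": "iii", "bvs-window": "iv"}[
                reason
            ]
            ledger.add(trimmed, stage, reason)
            continue
        ledger.add(trimmed, "kept", "kept")
        kept.append(trimmed)
    return kept, ledger
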