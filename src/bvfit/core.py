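"""The bond-valence model.

Single-bond valences, bond-valence sums (BVS), the closed-form R0 of a
homoleptic site, single-parameter ``delta R0`` shifts, typical metal-ligand
distances and first-sphere contribution cutoffs.  Everything here is pure
computation on the domain types; no I/O.

The valence of one metal-ligand bond of length ``d`` is

    v = exp[(R0 - d) / b]

with a bond-type-specific reference length ``R0`` and a global softness
``b`` (0.37 A unless configured otherwise).  The BVS of a site is the sum
of its contact valences and, under the sum rule, is expected to equal the
metal's oxidation state ``S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import (
    HeterolepticSiteError,
    InvalidArgumentError,
    MissingParameterError,
    NoFeasibleShiftError,
    UnassignedOxidationError,
)

DEFAULT_B = 0.37
"""Global softness parameter of the exponential bond length-valence law, A."""

R0_SANITY_WINDOW = (1.0, 3.5)
"""Open interval every stored R0 must lie in, A."""

SPIN_CLASSES = ("none", "LS", "HS")
SITE_SPIN_CLASSES = ("none", "LS", "HS", "unknown")

# Element symbols, H..Og.  Used only to validate inputs.
ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og D""".split()
)

# Elements we never treat as a coordinating metal centre.
NONMETALS = frozenset(
    "H D He B C N O F Ne Si P S Cl Ar As Se Br Kr Te I Xe At Rn".split()
)


def normalize_element(symbol: str) -> str:
    """Normalize an element symbol ('FE' -> 'Fe') and validate it."""
    sym = symbol.strip()
    if not sym:
        raise InvalidArgumentError("empty element symbol")
    sym = sym[0].upper() + sym[1:].lower()
    if sym not in ELEMENTS:
        raise InvalidArgumentError(f"unknown element symbol {symbol!r}")
    return sym


def is_metal(symbol: str) -> bool:
    return normalize_element(symbol) not in NONMETALS


@dataclass(frozen=True)
class LigandContact:
    """One metal -> ligand-atom contact."""

    ligand_element: str
    distance: float
    symmetry_generated: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "ligand_element", normalize_element(self.ligand_element)
        )
        if not (self.distance > 0):
            raise InvalidArgumentError(
                f"contact distance must be positive, got {self.distance}"
            )


@dataclass(frozen=True, order=True)
class BondTypeKey:
    """(metal species, ligand element) unit that a single R0 attaches to.

    The metal species includes the oxidation state and, where a split has
    been declared (Fe-N in both oxidation states), a spin class.
    """

    metal_element: str
    oxidation_state: int
    ligand_element: str
    spin_class: str = "none"

    def __post_init__(self):
        object.__setattr__(
            self, "metal_element", normalize_element(self.metal_element)
        )
        object.__setattr__(
            self, "ligand_element", normalize_element(self.ligand_element)
        )
        if not (isinstance(self.oxidation_state, int) and self.oxidation_state > 0):
            raise InvalidArgumentError(
                f"oxidation state must be a positive integer, got {self.oxidation_state}"
            )
        if self.spin_class not in SPIN_CLASSES:
            raise InvalidArgumentError(
                f"spin class must be one of {SPIN_CLASSES}, got {self.spin_class!r}"
            )

    def with_spin(self, spin_class: str) -> "BondTypeKey":
        return replace(self, spin_class=spin_class)

    def label(self) -> str:
        spin = f" {self.spin_class}" if self.spin_class != "none" else ""
        return f"{self.metal_element}({self.oxidation_state}){spin}-{self.ligand_element}"


@dataclass
class ParameterEntry:
    """One fitted/reference R0 with bookkeeping."""

    r0: float
    uncertainty: float = 0.0
    n_sites: int = 0
    valid_cn: Optional[int] = None  # e.g. Fe-S parameters only hold at CN = 4

    def __post_init__(self):
        lo, hi = R0_SANITY_WINDOW
        if not (lo < self.r0 < hi):
            raise InvalidArgumentError(
                f"R0 = {self.r0} A outside sanity window ({lo}, {hi})"
            )
        if self.uncertainty < 0:
            raise InvalidArgumentError("uncertainty must be nonnegative")


@dataclass
class ParameterSet:
    """Mapping BondTypeKey -> R0 entry, with the global softness b.

    Lookup is exact on the key; a missing key raises
    :class:`~bvfit.errors.MissingParameterError` rather than falling back
    to a spinless entry.  :meth:`resolve` implements the one sanctioned
    relaxation: a site labeled LS/HS may use the unsplit parameter for
    bond types that were never split (e.g. LS iron still uses the single
    Fe-O parameter).
    """

    b: float = DEFAULT_B
    entries: Dict[BondTypeKey, ParameterEntry] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.b > 0):
            raise InvalidArgumentError(f"b must be positive, got {self.b}")

    def set(
        self,
        key: BondTypeKey,
        r0: float,
        uncertainty: float = 0.0,
        n_sites: int = 0,
        valid_cn: Optional[int] = None,
    ) -> None:
        self.entries[key] = ParameterEntry(r0, uncertainty, n_sites, valid_cn)

    def r0(self, key: BondTypeKey) -> float:
        try:
            return self.entries[key].r0
        except KeyError:
            raise MissingParameterError(key) from None

    def __contains__(self, key: BondTypeKey) -> bool:
        return key in self.entries

    def resolve(
        self,
        metal_element: str,
        oxidation_state: int,
        ligand_element: str,
        spin_class: str = "none",
    ) -> BondTypeKey:
        """Resolve the key a contact should be scored with.

        A declared spin class (LS/HS) prefers the split key and may fall
        back to the unsplit one; an undeclared spin ("none"/"unknown")
        must resolve the unsplit key exactly.
        """
        base = BondTypeKey(metal_element, oxidation_state, ligand_element)
        if spin_class in ("LS", "HS"):
            split = base.with_spin(spin_class)
            if split in self.entries:
                return split
        if base in self.entries:
            return base
        raise MissingParameterError(
            base if spin_class in ("none", "unknown") else base.with_spin(spin_class)
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            b=self.b, entries={k: replace(v) for k, v in self.entries.items()}
        )

    def keys(self):
        return self.entries.keys()

    def __len__(self):
        return len(self.entries)


@dataclass
class BindingSite:
    """A metal centre with its ligand contacts and provenance metadata."""

    entry_id: str
    site_id: str
    metal_element: str
    contacts: List[LigandContact]
    oxidation_state: Optional[int] = None
    spin_class: str = "unknown"
    compound_name: str = ""
    r_factor: Optional[float] = None
    disordered: bool = False
    has_metal_carbon_bond: bool = False

    def __post_init__(self):
        self.metal_element = normalize_element(self.metal_element)
        if self.oxidation_state is not None:
            if not (
                isinstance(self.oxidation_state, int) and self.oxidation_state > 0
            ):
                raise InvalidArgumentError(
                    "oxidation_state must be a positive integer or None, "
                    f"got {self.oxidation_state!r}"
                )
        if self.spin_class not in SITE_SPIN_CLASSES:
            raise InvalidArgumentError(
                f"spin class must be one of {SITE_SPIN_CLASSES}, got {self.spin_class!r}"
            )
        if self.r_factor is not None and self.r_factor < 0:
            raise InvalidArgumentError("r_factor must be nonnegative")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.entry_id, self.site_id)

    @property
    def coordination_number(self) -> int:
        return len(self.contacts)

    def ligand_elements(self) -> List[str]:
        return [c.ligand_element for c in self.contacts]

    def is_homoleptic(self) -> bool:
        return len(set(self.ligand_elements())) == 1 and bool(self.contacts)

    def require_oxidation(self) -> int:
        if self.oxidation_state is None:
            raise UnassignedOxidationError(
                f"site {self.entry_id}/{self.site_id} has no assigned oxidation state"
            )
        return self.oxidation_state

    def resolved_keys(self, params: ParameterSet) -> List[BondTypeKey]:
        """Per-contact parameter keys under ``params`` (order-preserving)."""
        s = self.require_oxidation()
        return [
            params.resolve(self.metal_element, s, c.ligand_element, self.spin_class)
            for c in self.contacts
        ]

    def with_contacts(self, contacts: Iterable[LigandContact]) -> "BindingSite":
        return replace(self, contacts=list(contacts))

    def with_spin(self, spin_class: str) -> "BindingSite":
        return replace(self, spin_class=spin_class)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


def bond_valence(distance: float, r0: float, b: float = DEFAULT_B) -> float:
    """Valence of a single bond of length ``distance``: exp[(r0 - d)/b].

    Strictly decreasing in ``distance`` and strictly increasing in ``r0``.
    """
    if not (b > 0):
        raise InvalidArgumentError(f"b must be positive, got {b}")
    if not (distance > 0):
        raise InvalidArgumentError(f"distance must be positive, got {distance}")
    return math.exp((r0 - distance) / b)


def bvs(site: BindingSite, params: ParameterSet) -> float:
    """Bond-valence sum of a site: sum of its contact valences.

    Every contact's bond type must resolve in ``params``; an unresolvable
    type raises :class:`MissingParameterError` naming the key.
    """
    if not site.contacts:
        return 0.0
    keys = site.resolved_keys(params)
    return sum(
        bond_valence(c.distance, params.entries[k].r0, params.b)
        for c, k in zip(site.contacts, keys)
    )


def homoleptic_r0(site: BindingSite, b: float = DEFAULT_B) -> float:
    """Closed-form R0 of a homoleptic site: the unique value making BVS = S.

        R0 = b * [ln S - ln sum_j exp(-d_j / b)]
    """
    if not (b > 0):
        raise InvalidArgumentError(f"b must be positive, got {b}")
    if not site.contacts:
        raise InvalidArgumentError("site has no contacts")
    if not site.is_homoleptic():
        raise HeterolepticSiteError(
            f"site {site.entry_id}/{site.site_id} is heteroleptic: "
            f"{sorted(set(site.ligand_elements()))}"
        )
    s = site.require_oxidation()
    total = sum(math.exp(-c.distance / b) for c in site.contacts)
    return b * (math.log(s) - math.log(total))


def delta_r0(
    site: BindingSite, params: ParameterSet, target_type: BondTypeKey
) -> float:
    """Shift of one R0 parameter that makes the site's BVS equal S.

        dR0 = b * ln[1 + (S - V) / V_beta]

    where ``V`` is the current BVS and ``V_beta`` the summed valence of
    the contacts carrying ``target_type``.  Reduces to ``b * ln(S / V)``
    for homoleptic sites.
    """
    s = site.require_oxidation()
    keys = site.resolved_keys(params)
    if target_type not in keys:
        raise InvalidArgumentError(
            f"site {site.entry_id}/{site.site_id} has no contact of type "
            f"{target_type.label()}"
        )
    b = params.b
    v_total = 0.0
    v_beta = 0.0
    for contact, key in zip(site.contacts, keys):
        v = bond_valence(contact.distance, params.entries[key].r0, b)
        v_total += v
        if key == target_type:
            v_beta += v
    argument = 1.0 + (s - v_total) / v_beta
    if argument <= 0:
        raise NoFeasibleShiftError(
            f"no shift of {target_type.label()} can bring BVS {v_total:.3f} "
            f"to S = {s} at site {site.entry_id}/{site.site_id}"
        )
    return b * math.log(argument)


def typical_distance(
    r0: float,
    oxidation_state: int,
    coordination_number: int,
    b: float = DEFAULT_B,
) -> float:
    """Distance at which n equal bond-valence contributions sum to S.

        d = R0 - b * ln(S / n)
    """
    if not (b > 0):
        raise InvalidArgumentError(f"b must be positive, got {b}")
    if coordination_number < 1:
        raise InvalidArgumentError("coordination number must be >= 1")
    if oxidation_state < 1:
        raise InvalidArgumentError("oxidation state must be >= 1")
    return r0 - b * math.log(oxidation_state / coordination_number)


def cutoff_distance(
    r0: float,
    oxidation_state: int,
    b: float = DEFAULT_B,
    fraction: float = 0.05,
) -> float:
    """First-sphere cutoff: distance where one contact has valence f*S.

        d_cutoff = R0 - b * [ln(fraction) + ln(S)]

    A contact beyond this distance would contribute less than ``fraction``
    of a perfectly-summing site's BVS and is presumed outside the first
    coordination sphere.
    """
    if not (b > 0):
        raise InvalidArgumentError(f"b must be positive, got {b}")
    if not (0 < fraction < 1):
        raise InvalidArgumentError(f"fraction must be in (0, 1), got {fraction}")
    if oxidation_state < 1:
        raise InvalidArgumentError("oxidation state must be >= 1")
    return r0 - b * (math.log(fraction) + math.log(oxidation_state))
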