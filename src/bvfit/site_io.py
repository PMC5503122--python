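"""Readers and writers for site tables and parameter tables, plus
coordination-sphere extraction from macromolecular coordinate files.

The site table is a CSV with one metal-ligand contact per row and ten
documented columns (see :data:`SITE_TABLE_COLUMNS`); rows sharing
``(entry_id, site_id)`` form one binding site.  Parameter tables mirror
the published layout: per bond type, homoleptic statistics, the optimized
R0 with its uncertainty, counts, the literature value and a significance
flag for |fit - literature| > 0.1 A.
"""

from __future__ import annotations

import csv
import io
import logging
import os
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    DEFAULT_B,
    BindingSite,
    BondTypeKey,
    LigandContact,
    ParameterSet,
    is_metal,
    normalize_element,
)
from .errors import InvalidArgumentError
from .reference import brese_okeeffe_params

logger = logging.getLogger(__name__)

SITE_TABLE_COLUMNS = [
    "entry_id",
    "site_id",
    "metal_element",
    "compound_name",
    "r_factor",
    "disorder_flag",
    "metal_carbon_flag",
    "ligand_element",
    "distance_angstrom",
    "symmetry_flag",
]

SIGNIFICANCE_THRESHOLD = 0.1  # A; |fit - literature| beyond this is flagged

PARAMETER_TABLE_COLUMNS = [
    "metal_element",
    "oxidation_state",
    "spin_class",
    "ligand_element",
    "n_homoleptic",
    "homoleptic_r0_mean",
    "homoleptic_r0_sd",
    "r0",
    "uncertainty",
    "n_sites",
    "valid_cn",
    "literature_r0",
    "significant",
]

PathOrBuffer = Union[str, os.PathLike, io.TextIOBase]


def _parse_bool(value: str, line: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f", ""):
        return False
    raise InvalidArgumentError(
        f"line {line}: cannot parse {column}={value!r} as a boolean"
    )


def _normalize_r_factor(value: float) -> float:
    """Accept percent-style R factors (7.5 -> 0.075), logging the conversion."""
    if value > 1.0:
        logger.info("normalizing percent-style R factor %s -> %s", value, value / 100)
        return value / 100.0
    return value


def read_site_table(source: PathOrBuffer) -> List[BindingSite]:
    """Read a contact-per-row site table into BindingSites.

    Rows are grouped by (entry_id, site_id) in order of first appearance;
    row order within a site is preserved.  Duplicate contact rows are kept
    (symmetry contacts are legitimate duplicates by distance).  Malformed
    rows raise with their line number.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        handle = open(source, "r", newline="", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise InvalidArgumentError("site table is empty (no header)")
        missing = [c for c in SITE_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InvalidArgumentError(
                f"site table missing column(s): {', '.join(missing)}"
            )
        groups: Dict[Tuple[str, str], Dict[str, object]] = {}
        order: List[Tuple[str, str]] = []
        for line_no, row in enumerate(reader, start=2):
            try:
                distance = float(row["distance_angstrom"])
            except (TypeError, ValueError):
                raise InvalidArgumentError(
                    f"line {line_no}: bad distance {row.get('distance_angstrom')!r}"
                ) from None
            if distance <= 0:
                raise InvalidArgumentError(
                    f"line {line_no}: non-positive distance {distance}"
                )
            r_raw = (row.get("r_factor") or "").strip()
            if r_raw == "":
                r_factor: Optional[float] = None
            else:
                try:
                    r_factor = _normalize_r_factor(float(r_raw))
                except ValueError:
                    raise InvalidArgumentError(
                        f"line {line_no}: bad r_factor {r_raw!r}"
                    ) from None
            key = (str(row["entry_id"]), str(row["site_id"]))
            contact = LigandContact(
                ligand_element=normalize_element(str(row["ligand_element"])),
                distance=distance,
                symmetry_generated=_parse_bool(
                    row.get("symmetry_flag", ""), line_no, "symmetry_flag"
                ),
            )
            if key not in groups:
                order.append(key)
                groups[key] = {
                    "metal_element": normalize_element(str(row["metal_element"])),
                    "compound_name": str(row.get("compound_name") or ""),
                    "r_factor": r_factor,
                    "disordered": _parse_bool(
                        row.get("disorder_flag", ""), line_no, "disorder_flag"
                    ),
                    "has_metal_carbon_bond": _parse_bool(
                        row.get("metal_carbon_flag", ""), line_no, "metal_carbon_flag"
                    ),
                    "contacts": [],
                }
            groups[key]["contacts"].append(contact)  # type: ignore[union-attr]
        return [
            BindingSite(
                entry_id=entry_id,
                site_id=site_id,
                metal_element=groups[(entry_id, site_id)]["metal_element"],  # type: ignore[arg-type]
                contacts=groups[(entry_id, site_id)]["contacts"],  # type: ignore[arg-type]
                compound_name=groups[(entry_id, site_id)]["compound_name"],  # type: ignore[arg-type]
                r_factor=groups[(entry_id, site_id)]["r_factor"],  # type: ignore[arg-type]
                disordered=groups[(entry_id, site_id)]["disordered"],  # type: ignore[arg-type]
                has_metal_carbon_bond=groups[(entry_id, site_id)][
                    "has_metal_carbon_bond"
                ],  # type: ignore[arg-type]
            )
            for entry_id, site_id in order
        ]
    finally:
        if close:
            handle.close()


def write_site_table(sites: Iterable[BindingSite], destination: PathOrBuffer) -> None:
    """Write sites as the standard contact-per-row CSV (full float precision)."""
    close = False
    if isinstance(destination, (str, os.PathLike)):
        handle = open(destination, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for site in sites:
            for contact in site.contacts:
                writer.writerow(
                    [
                        site.entry_id,
                        site.site_id,
                        site.metal_element,
                        site.compound_name,
                        "" if site.r_factor is None else repr(float(site.r_factor)),
                        site.disordered,
                        site.has_metal_carbon_bond,
                        contact.ligand_element,
                        repr(float(contact.distance)),
                        contact.symmetry_generated,
                    ]
                )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Coordination-sphere extraction from coordinate files
# ---------------------------------------------------------------------------


def extract_sites_from_structure(
    coordinates: Union[str, os.PathLike],
    metal_elements: Sequence[str] = ("Fe",),
    radius: float = 4.0,
) -> List[BindingSite]:
    """Extract one BindingSite per metal atom from a PDB/mmCIF file.

    Contacts are all non-carbon, non-hydrogen, non-metal atoms within
    ``radius`` A (Euclidean, asymmetric unit only).  Oxidation state is
    left unassigned; the compound name is the structure title when
    available.  Returns an empty list (logged) when no metal is found.
    """
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.NeighborSearch import NeighborSearch

    if radius < 0:
        raise InvalidArgumentError("radius must be nonnegative")
    path = os.fspath(coordinates)
    wanted = {normalize_element(e) for e in metal_elements}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.lower().endswith((".cif", ".mmcif")):
            parser = MMCIFParser(QUIET=True)
        else:
            parser = PDBParser(QUIET=True)
        structure = parser.get_structure("structure", path)
    header = getattr(structure, "header", None) or {}
    compound_name = str(header.get("name") or "").strip()

    atoms = list(structure.get_atoms())
    for atom in atoms:
        if not atom.element:  # infer from the atom name if needed
            atom.element = atom.get_name().strip()[:2]

    def element_of(atom) -> Optional[str]:
        try:
            return normalize_element(str(atom.element))
        except InvalidArgumentError:
            return None

    metals = [a for a in atoms if element_of(a) in wanted]
    if not metals:
        logger.info("no metal atoms (%s) found in %s", sorted(wanted), path)
        return []
    search = NeighborSearch(atoms) if radius > 0 else None

    sites = []
    for metal in metals:
        residue = metal.get_parent()
        chain = residue.get_parent()
        site_id = (
            f"{chain.id}_{residue.get_resname().strip()}"
            f"{residue.get_id()[1]}_{metal.get_name().strip()}"
        )
        contacts = []
        neighbours = search.search(metal.coord, radius) if search else []
        for atom in neighbours:
            if atom is metal:
                continue
            element = element_of(atom)
            if element is None or element in ("C", "H", "D"):
                continue
            if is_metal(element):
                continue
            distance = float(np.linalg.norm(atom.coord - metal.coord))
            if distance <= 0:
                continue
            contacts.append(LigandContact(element, distance))
        contacts.sort(key=lambda c: c.distance)
        sites.append(
            BindingSite(
                entry_id=os.path.splitext(os.path.basename(path))[0],
                site_id=site_id,
                metal_element=element_of(metal),
                contacts=contacts,
                compound_name=compound_name,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------


def write_parameter_table(
    params: ParameterSet,
    destination: PathOrBuffer,
    homoleptic: Optional[Dict[BondTypeKey, Dict[str, float]]] = None,
    literature: Optional[ParameterSet] = None,
) -> None:
    """Emit the published-style parameter table as CSV.

    One row per bond type: homoleptic mean (sd) and count, optimized R0
    with its uncertainty and site count, the literature reference value,
    and a flag when |fit - literature| > 0.1 A.
    """
    literature = literature if literature is not None else brese_okeeffe_params()
    homoleptic = homoleptic or {}
    close = False
    if isinstance(destination, (str, os.PathLike)):
        handle = open(destination, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PARAMETER_TABLE_COLUMNS)
        for key in sorted(params.keys()):
            entry = params.entries[key]
            stats = homoleptic.get(key)
            lit_key = key.with_spin("none")
            lit_r0 = (
                literature.entries[lit_key].r0 if lit_key in literature else None
            )
            significant = (
                abs(entry.r0 - lit_r0) > SIGNIFICANCE_THRESHOLD
                if lit_r0 is not None
                else ""
            )
            writer.writerow(
                [
                    key.metal_element,
                    key.oxidation_state,
                    key.spin_class,
                    key.ligand_element,
                    stats["count"] if stats else "",
                    repr(stats["mean"]) if stats else "",
                    repr(stats["sd"]) if stats else "",
                    repr(entry.r0),
                    repr(entry.uncertainty),
                    entry.n_sites,
                    "" if entry.valid_cn is None else entry.valid_cn,
                    "" if lit_r0 is None else repr(lit_r0),
                    significant,
                ]
            )
    finally:
        if close:
            handle.close()


def read_parameter_table(source: PathOrBuffer, b: float = DEFAULT_B) -> ParameterSet:
    """Read a parameter-table CSV back into a ParameterSet."""
    close = False
    if isinstance(source, (str, os.PathLike)):
        handle = open(source, "r", newline="", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        reader = csv.DictReader(handle)
        params = ParameterSet(b=b)
        for line_no, row in enumerate(reader, start=2):
            try:
                key = BondTypeKey(
                    row["metal_element"],
                    int(row["oxidation_state"]),
                    row["ligand_element"],
                    row.get("spin_class") or "none",
                )
                valid_cn_raw = (row.get("valid_cn") or "").strip()
                params.set(
                    key,
                    float(row["r0"]),
                    uncertainty=float(row.get("uncertainty") or 0.0),
                    n_sites=int(row.get("n_sites") or 0),
                    valid_cn=int(valid_cn_raw) if valid_cn_raw else None,
                )
            except (KeyError, ValueError) as exc:
                raise InvalidArgumentError(
                    f"line {line_no}: malformed parameter row ({exc})"
                ) from None
        return params
    finally:
        if close:
            handle.close()


def write_truth_ledger(
    truth: List[Dict[str, object]], destination: PathOrBuffer
) -> None:
    """Write a synthetic ground-truth ledger as CSV."""
    close = False
    if isinstance(destination, (str, os.PathLike)):
        handle = open(destination, "w", newline="", encoding="utf-8")
        close = True
    else:
        handle = destination
    try:
        if not truth:
            handle.write("")
            return
        writer = csv.DictWriter(
            handle, fieldnames=list(truth[0].keys()), lineterminator="\n"
        )
        writer.writeheader()
        writer.writerows(truth)
    finally:
        if close:
            handle.close()
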