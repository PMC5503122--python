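"""Synthetic site populations with the statistical structure the fit assumes.

Sites are generated backwards from the model: a valence partition summing
to the oxidation state is drawn (equal shares, optionally jittered by a
symmetric Dirichlet scaled to S), each share is converted to a distance
via d = R0 - b*ln(v), and Gaussian noise is added on the distances.
Optional features: heteroleptic ligand mixes, a two-spin-population split
(LS/HS), and planted outlier sites that violate the (0, 2S) BVS window to
exercise in-fit pruning.  Everything is reproducible from the seed, and a
ground-truth ledger records every generating value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import BindingSite, LigandContact, ParameterSet
from .errors import ConfigError, MissingParameterError

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII"}
_METAL_NAME = {
    "Fe": "iron", "Na": "sodium", "Mg": "magnesium",
    "K": "potassium", "Ca": "calcium", "Zn": "zinc",
}


@dataclass
class SyntheticConfig:
    true_params: ParameterSet
    n_sites: int
    metal_element: str = "Fe"
    oxidation_state: int = 2
    cn_distribution: Dict[int, float] = field(default_factory=lambda: {6: 1.0})
    heteroleptic_fraction: float = 0.0
    ligand_pool: Dict[str, float] = field(default_factory=lambda: {"N": 1.0})
    distance_noise_sd: float = 0.0
    partition_jitter: Optional[float] = None  # Dirichlet concentration; None = equal
    spin_populations: Optional[Dict[str, float]] = None  # {"ls_fraction": x}
    outlier_fraction: float = 0.0
    outlier_factor: float = 2.5  # planted outliers get BVS = factor * S
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 0:
            raise ConfigError("n_sites must be nonnegative")
        if self.distance_noise_sd < 0:
            raise ConfigError("distance_noise_sd must be nonnegative")
        if not (0 <= self.heteroleptic_fraction <= 1):
            raise ConfigError("heteroleptic_fraction must be in [0, 1]")
        if not (0 <= self.outlier_fraction <= 1):
            raise ConfigError("outlier_fraction must be in [0, 1]")
        total = sum(self.cn_distribution.values())
        if total <= 0 or any(p < 0 for p in self.cn_distribution.values()):
            raise ConfigError("cn_distribution must be a nonnegative distribution")
        self.cn_distribution = {
            n: p / total for n, p in self.cn_distribution.items()
        }
        if any(n < 2 or n > 8 for n in self.cn_distribution):
            raise ConfigError("coordination numbers must lie in 2..8")
        wtotal = sum(self.ligand_pool.values())
        if wtotal <= 0:
            raise ConfigError("ligand_pool weights must sum to > 0")
        self.ligand_pool = {e: w / wtotal for e, w in self.ligand_pool.items()}
        if self.partition_jitter is not None and self.partition_jitter <= 0:
            raise ConfigError("partition_jitter must be positive when set")
        if self.spin_populations is not None:
            ls = self.spin_populations.get("ls_fraction")
            if ls is None or not (0 <= ls <= 1):
                raise ConfigError("spin_populations needs ls_fraction in [0, 1]")


def _resolve_r0(config: SyntheticConfig, ligand: str, spin: str) -> float:
    params = config.true_params
    try:
        key = params.resolve(
            config.metal_element, config.oxidation_state, ligand, spin
        )
    except MissingParameterError:
        raise ConfigError(
            f"true_params lacks a parameter for "
            f"{config.metal_element}({config.oxidation_state})"
            f"{'' if spin == 'none' else ' ' + spin}-{ligand}"
        ) from None
    return params.entries[key].r0


def generate_population(
    config: SyntheticConfig,
) -> Tuple[List[BindingSite], List[Dict[str, object]]]:
    """Generate a population and its ground-truth ledger.

    Ledger rows record, per site: coordination number, spin class, outlier
    flag, and the generating valence partition and noise-free distances.
    """
    rng = np.random.default_rng(config.seed)
    b = config.true_params.b
    s = config.oxidation_state
    cns = sorted(config.cn_distribution)
    cn_probs = [config.cn_distribution[n] for n in cns]
    pool = sorted(config.ligand_pool)
    pool_probs = [config.ligand_pool[e] for e in pool]
    metal_name = _METAL_NAME.get(config.metal_element, config.metal_element.lower())

    sites: List[BindingSite] = []
    truth: List[Dict[str, object]] = []
    for i in range(config.n_sites):
        cn = int(rng.choice(cns, p=cn_probs))
        heteroleptic = (
            len(pool) > 1 and rng.random() < config.heteroleptic_fraction
        )
        if heteroleptic:
            elements = [str(rng.choice(pool, p=pool_probs)) for _ in range(cn)]
            if len(set(elements)) == 1:  # force a genuine mix
                other = [e for e in pool if e != elements[0]]
                elements[int(rng.integers(cn))] = str(
                    rng.choice(other, p=None)
                )
        else:
            elements = [str(rng.choice(pool, p=pool_probs))] * cn

        spin = "none"
        if config.spin_populations is not None:
            spin = (
                "LS"
                if rng.random() < config.spin_populations["ls_fraction"]
                else "HS"
            )

        if config.partition_jitter is None:
            valences = np.full(cn, s / cn)
        else:
            valences = rng.dirichlet([config.partition_jitter] * cn) * s
            valences = np.maximum(valences, 1e-9)

        distances = []
        for element, v in zip(elements, valences):
            r0 = _resolve_r0(config, element, spin)
            if v >= math.exp(r0 / b):
                raise ConfigError(
                    f"valence share {v:.3g} implies a non-positive distance "
                    f"for R0 = {r0} A"
                )
            distances.append(r0 - b * math.log(v))
        clean_distances = list(distances)

        is_outlier = rng.random() < config.outlier_fraction
        if is_outlier:
            # uniform shift scaling every valence by outlier_factor
            shift = b * math.log(config.outlier_factor)
            distances = [d - shift for d in distances]
        if config.distance_noise_sd > 0:
            noise = rng.normal(0.0, config.distance_noise_sd, size=cn)
            distances = [d + e for d, e in zip(distances, noise)]
        if any(d <= 0 for d in distances):
            raise ConfigError("generated a non-positive distance; reduce noise")

        entry_id = f"SYN{i:05d}"
        site = BindingSite(
            entry_id=entry_id,
            site_id="M1",
            metal_element=config.metal_element,
            contacts=[
                LigandContact(e, float(d)) for e, d in zip(elements, distances)
            ],
            oxidation_state=None,  # assigned downstream from the name
            spin_class="unknown",
            compound_name=(
                f"synthetic {metal_name}({_ROMAN[s]}) complex {i}"
            ),
            r_factor=0.02,
            disordered=False,
            has_metal_carbon_bond=False,
        )
        sites.append(site)
        truth.append(
            {
                "entry_id": entry_id,
                "site_id": "M1",
                "oxidation_state": s,
                "spin_class": spin,
                "coordination_number": cn,
                "heteroleptic": heteroleptic,
                "is_outlier": is_outlier,
                "valences": ";".join(f"{v:.12g}" for v in valences),
                "clean_distances": ";".join(f"{d:.12g}" for d in clean_distances),
            }
        )
    return sites, truth


def generate_spin_mixture(
    config: SyntheticConfig,
) -> Tuple[List[BindingSite], List[Dict[str, object]]]:
    """Population with two spin populations of the split bond type(s).

    Requires ``spin_populations`` and LS/HS entries in ``true_params``;
    its single-parameter BVS histogram is bimodal with the secondary
    (low-spin) mode above the oxidation state.
    """
    if config.spin_populations is None:
        raise ConfigError("generate_spin_mixture requires spin_populations")
    has_split = any(
        key.spin_class in ("LS", "HS")
        and key.metal_element == config.metal_element
        and key.oxidation_state == config.oxidation_state
        for key in config.true_params.keys()
    )
    if not has_split:
        raise ConfigError(
            "true_params carries no spin-split bond type for "
            f"{config.metal_element}({config.oxidation_state})"
        )
    return generate_population(config)
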