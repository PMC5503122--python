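"""Simultaneous R0 optimization over homoleptic and heteroleptic sites.

For one metal species (a metal element in one oxidation state, optionally
split by spin class) the objective is the summed squared deviation of the
bond-valence sums around the expected oxidation states,

    sigma^2 = sum_i (V_i - S_i)^2,

minimized over all R0 parameters of that species at once by nonlinear
conjugate gradients with an analytic gradient,

    d sigma^2 / d R0_beta = (2 / b) * sum_i (V_i - S_i) * V_{i,beta},

where V_{i,beta} is the summed valence of the type-beta contacts of site
i.  Between converged passes, sites whose BVS falls outside (0, 2S) under
the *current* parameters are pruned and the fit restarts (criterion iv).

Per-type uncertainties are the root mean square of the single-parameter
shifts ``delta_r0`` that would make each supporting site's BVS exact; this
upper-bounds the parameter standard deviation.

``split_bimodal`` resolves a bimodal BVS population (low-spin vs high-spin
iron-nitrogen bonds) into two parameters: a deterministic two-component
equal-variance Gaussian mixture on the single-parameter BVS values seeds
hard assignments, the bond type is duplicated into LS/HS keys, and the
assignments and joint refit are iterated to a fixed point (hard EM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .core import (
    BindingSite,
    BondTypeKey,
    ParameterSet,
    bond_valence,
    bvs,
    delta_r0,
    homoleptic_r0,
)
from .curation import FilterConfig, FilterLedger
from .errors import (
    ConfigError,
    ConvergenceError,
    EmptyBondTypeError,
    NoFeasibleShiftError,
)


@dataclass
class FitConfig:
    """Optimizer settings."""

    gradient_tolerance: float = 1e-8  # on max |d sigma^2 / d R0|
    max_iterations: int = 10_000
    restart_pruning: bool = True
    max_prune_passes: int = 20
    line_search: str = "strong-wolfe"  # scipy CG uses a strong-Wolfe search
    seed: int = 0
    # spin-split settings
    min_separation_vu: float = 0.3  # mixture means closer than this: no split
    max_split_rounds: int = 10
    split_method: str = "gmm"  # or "valley" (threshold at the histogram valley)

    def __post_init__(self):
        if self.gradient_tolerance <= 0:
            raise ConfigError("gradient_tolerance must be positive")
        if self.max_iterations <= 0:
            raise ConfigError("max_iterations must be positive")
        if self.split_method not in ("gmm", "valley"):
            raise ConfigError("split_method must be 'gmm' or 'valley'")


@dataclass
class UncertaintyResult:
    """Per-type RMS |delta R0| with skip diagnostics."""

    values: Dict[BondTypeKey, float]
    n_used: Dict[BondTypeKey, int]
    n_skipped: Dict[BondTypeKey, int]
    undefined: List[BondTypeKey]


@dataclass
class FitResult:
    params: ParameterSet
    objective_trace: List[float]
    pruned_sites: FilterLedger
    uncertainties: Dict[BondTypeKey, float]
    n_sites_used: Dict[BondTypeKey, int]
    n_prune_passes: int = 0
    converged: bool = True
    sites_used: List[BindingSite] = field(default_factory=list)


@dataclass
class SpinSplitResult:
    split: bool
    assignments: Dict[Tuple[str, str], str]  # (entry_id, site_id) -> LS/HS
    params: ParameterSet
    separation: float
    mixture_means: Tuple[float, float]
    mixture_sigma: float
    mixture_weights: Tuple[float, float]
    bvs_values: Dict[Tuple[str, str], float]
    histogram: Tuple[np.ndarray, np.ndarray]
    fit: Optional[FitResult] = None
    rounds: int = 0


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------


def _site_type_valences(
    site: BindingSite, params: ParameterSet
) -> Dict[BondTypeKey, float]:
    """Summed valence per resolved bond type at one site."""
    out: Dict[BondTypeKey, float] = {}
    for contact, key in zip(site.contacts, site.resolved_keys(params)):
        v = bond_valence(contact.distance, params.entries[key].r0, params.b)
        out[key] = out.get(key, 0.0) + v
    return out


def objective(params: ParameterSet, sites: Sequence[BindingSite]) -> float:
    """sigma^2 = sum_i (V_i - S_i)^2."""
    total = 0.0
    for site in sites:
        total += (bvs(site, params) - site.require_oxidation()) ** 2
    return total


def gradient(
    params: ParameterSet, sites: Sequence[BindingSite]
) -> Dict[BondTypeKey, float]:
    """Analytic gradient of the objective w.r.t. every parameter in use.

    Types present in no site get an (exactly zero) component.
    """
    grad: Dict[BondTypeKey, float] = {key: 0.0 for key in params.keys()}
    for site in sites:
        per_type = _site_type_valences(site, params)
        residual = sum(per_type.values()) - site.require_oxidation()
        for key, v_beta in per_type.items():
            grad[key] += 2.0 * residual * v_beta / params.b
    return grad


class _Problem:
    """Vectorized objective/gradient over a fixed key ordering.

    Precomputes, per site, the contact distances and a contact->key index
    so the optimizer's inner loop is pure numpy.
    """

    def __init__(self, sites: Sequence[BindingSite], params: ParameterSet):
        self.b = params.b
        self.keys: List[BondTypeKey] = sorted(
            {k for site in sites for k in site.resolved_keys(params)}
        )
        self.key_index = {k: i for i, k in enumerate(self.keys)}
        self.site_data = []
        for site in sites:
            d = np.array([c.distance for c in site.contacts], dtype=float)
            idx = np.array(
                [self.key_index[k] for k in site.resolved_keys(params)], dtype=int
            )
            self.site_data.append((d, idx, float(site.require_oxidation())))
        self.n_params = len(self.keys)

    def x0(self, params: ParameterSet) -> np.ndarray:
        return np.array([params.entries[k].r0 for k in self.keys])

    def value_and_grad(self, x: np.ndarray) -> Tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(self.n_params)
        for d, idx, s in self.site_data:
            v = np.exp((x[idx] - d) / self.b)
            residual = v.sum() - s
            total += residual * residual
            np.add.at(grad, idx, 2.0 * residual * v / self.b)
        return total, grad

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """Exact Hessian: (2/b^2) sum_i [V_b V_g + delta_bg (V_i - S_i) V_b]."""
        h = np.zeros((self.n_params, self.n_params))
        for d, idx, s in self.site_data:
            v = np.exp((x[idx] - d) / self.b)
            v_by_type = np.zeros(self.n_params)
            np.add.at(v_by_type, idx, v)
            residual = v.sum() - s
            h += np.outer(v_by_type, v_by_type)
            h[np.diag_indices_from(h)] += residual * v_by_type
        return 2.0 * h / (self.b * self.b)

    def params_at(self, x: np.ndarray, template: ParameterSet) -> ParameterSet:
        out = template.copy()
        for key, r0 in zip(self.keys, x):
            entry = out.entries[key]
            out.entries[key] = replace(entry, r0=float(r0))
        return out


def _minimize(
    sites: Sequence[BindingSite], initial: ParameterSet, config: FitConfig
) -> Tuple[ParameterSet, List[float], bool]:
    problem = _Problem(sites, initial)
    x0 = problem.x0(initial)
    trace: List[float] = [problem.value_and_grad(x0)[0]]

    def callback(xk):
        trace.append(problem.value_and_grad(xk)[0])

    res = optimize.minimize(
        lambda x: problem.value_and_grad(x),
        x0,
        jac=True,
        method="CG",
        callback=callback,
        options={
            "gtol": config.gradient_tolerance,
            "maxiter": config.max_iterations,
        },
    )
    # Newton polish: scipy's CG line search bottoms out around |grad| ~ 1e-6
    # on noisy data; a few exact-Hessian steps reach the stated tolerance.
    x = res.x.copy()
    f, g = problem.value_and_grad(x)
    for _ in range(100):
        if np.max(np.abs(g)) <= config.gradient_tolerance:
            break
        h = problem.hessian(x)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        # backtracking keeps the trace monotone even far from the optimum;
        # at the floating-point floor a step may raise f by rounding noise
        # while still shrinking the gradient -- accept those too
        alpha = 1.0
        accepted = False
        for _ in range(60):
            f_new, g_new = problem.value_and_grad(x - alpha * step)
            if f_new <= f or (
                np.max(np.abs(g_new)) < np.max(np.abs(g))
                and f_new <= f + 1e-10 * (1.0 + abs(f))
            ):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        if f_new < f:
            trace.append(f_new)
        x, f, g = x - alpha * step, f_new, g_new
    converged = bool(np.max(np.abs(g)) <= config.gradient_tolerance)
    params = problem.params_at(x, initial)
    if not converged:
        raise ConvergenceError(
            f"conjugate gradients did not reach gtol={config.gradient_tolerance} "
            f"in {config.max_iterations} iterations (max |grad| = {np.max(np.abs(g)):.3e})",
            best_result=FitResult(
                params=params,
                objective_trace=trace,
                pruned_sites=FilterLedger(),
                uncertainties={},
                n_sites_used=_count_sites(sites, params),
                converged=False,
                sites_used=list(sites),
            ),
        )
    return params, trace, converged


def _count_sites(
    sites: Sequence[BindingSite], params: ParameterSet
) -> Dict[BondTypeKey, int]:
    counts: Dict[BondTypeKey, int] = {}
    for site in sites:
        for key in set(site.resolved_keys(params)):
            counts[key] = counts.get(key, 0) + 1
    return counts


def fit_r0(
    sites: Sequence[BindingSite],
    initial: ParameterSet,
    config: Optional[FitConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> FitResult:
    """Fit all R0 parameters appearing in ``sites`` simultaneously.

    Starts from ``initial`` (literature values), converges by nonlinear
    conjugate gradients, then -- when ``config.restart_pruning`` -- applies
    criterion (iv) with the current parameters, drops violators into the
    prune ledger and restarts, until a fixed point or ``max_prune_passes``.
    """
    config = config or FitConfig()
    window = (filter_config or FilterConfig()).bvs_window_multiplier
    current = list(sites)
    if not current:
        raise ConfigError("no sites to fit")
    ledger = FilterLedger()
    trace: List[float] = []
    params = initial
    passes = 0
    while True:
        if not current:
            raise EmptyBondTypeError("pruning removed every site")
        params, pass_trace, _ = _minimize(current, initial, config)
        trace.extend(pass_trace)
        if not config.restart_pruning or passes >= config.max_prune_passes:
            break
        violators = [
            site
            for site in current
            if not (0 < bvs(site, params) < window * site.require_oxidation())
        ]
        if not violators:
            break
        passes += 1
        bad = {site.key for site in violators}
        for site in violators:
            ledger.add(site, "iv", "bvs-window", prune_pass=passes)
        survivors = [site for site in current if site.key not in bad]
        before = set(_count_sites(current, params))
        after = set(_count_sites(survivors, params)) if survivors else set()
        lost = before - after
        if lost:
            raise EmptyBondTypeError(
                "pruning removed all sites for bond type(s): "
                + ", ".join(k.label() for k in sorted(lost))
            )
        current = survivors
    unc = uncertainty(current, params)
    for key, entry in params.entries.items():
        params.entries[key] = replace(
            entry,
            uncertainty=unc.values.get(key, 0.0),
            n_sites=_count_sites(current, params).get(key, 0),
        )
    return FitResult(
        params=params,
        objective_trace=trace,
        pruned_sites=ledger,
        uncertainties=unc.values,
        n_sites_used=_count_sites(current, params),
        n_prune_passes=passes,
        converged=True,
        sites_used=current,
    )


def uncertainty(
    sites: Sequence[BindingSite], params: ParameterSet
) -> UncertaintyResult:
    """RMS single-parameter shift per bond type: sqrt(mean |delta R0|^2).

    Sites where no feasible shift exists are skipped and counted; a type
    with no feasible site at all is reported as undefined.
    """
    sums: Dict[BondTypeKey, float] = {}
    n_used: Dict[BondTypeKey, int] = {}
    n_skipped: Dict[BondTypeKey, int] = {}
    for site in sites:
        for key in set(site.resolved_keys(params)):
            try:
                shift = delta_r0(site, params, key)
            except NoFeasibleShiftError:
                n_skipped[key] = n_skipped.get(key, 0) + 1
                continue
            sums[key] = sums.get(key, 0.0) + shift * shift
            n_used[key] = n_used.get(key, 0) + 1
    values = {key: math.sqrt(sums[key] / n_used[key]) for key in sums}
    undefined = [key for key in n_skipped if key not in values]
    return UncertaintyResult(values, n_used, n_skipped, undefined)


def homoleptic_summary(
    sites: Sequence[BindingSite], b: float
) -> Dict[BondTypeKey, Dict[str, float]]:
    """Per-bond-type mean/sd/count of closed-form R0 over homoleptic sites.

    The key carries the site's spin class when one is assigned.  Sample
    standard deviation (ddof=1); 0.0 for singleton types.
    """
    per_type: Dict[BondTypeKey, List[float]] = {}
    for site in sites:
        if not site.is_homoleptic():
            continue
        spin = site.spin_class if site.spin_class in ("LS", "HS") else "none"
        key = BondTypeKey(
            site.metal_element,
            site.require_oxidation(),
            site.contacts[0].ligand_element,
            spin,
        )
        per_type.setdefault(key, []).append(homoleptic_r0(site, b))
    out = {}
    for key, values in per_type.items():
        arr = np.asarray(values)
        out[key] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "count": len(arr),
        }
    return out


# ---------------------------------------------------------------------------
# Bimodal (spin-state) splitting
# ---------------------------------------------------------------------------


def _em_two_gaussians(
    x: np.ndarray, max_iter: int = 500, tol: float = 1e-12
) -> Tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Equal-variance two-component 1-D Gaussian mixture, deterministic.

    Initialized at the 25th/75th percentiles.  Returns (means, sigma,
    weights, responsibilities (2, n)).
    """
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu[1] = mu[0] + 1e-6
    sigma = max(float(x.std()), 1e-6)
    w = np.array([0.5, 0.5])
    resp = np.full((2, len(x)), 0.5)
    prev = -np.inf
    for _ in range(max_iter):
        # E step: responsibilities under shared sigma
        z = np.stack([-0.5 * ((x - m) / sigma) ** 2 for m in mu])
        z += np.log(w)[:, None]
        zmax = z.max(axis=0)
        log_norm = zmax + np.log(np.exp(z - zmax).sum(axis=0))
        resp = np.exp(z - log_norm)
        loglik = float(log_norm.sum()) - len(x) * math.log(
            sigma * math.sqrt(2 * math.pi)
        )
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x).sum(axis=1) / nk
        var = float((resp * (x - mu[:, None]) ** 2).sum() / len(x))
        sigma = max(math.sqrt(var), 1e-9)
        w = nk / len(x)
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    return mu, sigma, w, resp


def _valley_threshold(x: np.ndarray) -> float:
    """Histogram-valley split point (alternative to the mixture)."""
    counts, edges = np.histogram(x, bins=max(10, len(x) // 20))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    # deepest bin between the global peak and the far mode on the other side
    right = counts[peak + 1 :]
    if len(right) == 0:
        return float(centers[peak])
    far = peak + 1 + int(np.argmax(right))
    if far <= peak + 1:
        return float(centers[peak])
    valley = peak + 1 + int(np.argmin(counts[peak + 1 : far]))
    return float(centers[valley])


def split_bimodal(
    sites: Sequence[BindingSite],
    bond_type: BondTypeKey,
    single_fit: FitResult,
    config: Optional[FitConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> SpinSplitResult:
    """Resolve a spin-split bond type from its bimodal BVS population.

    The single-parameter BVS of every site containing ``bond_type`` is
    mixture-modelled; the higher-BVS component is low spin (shorter bonds
    inflate the sum).  The bond type is duplicated into LS/HS keys, each
    initialized by the homoleptic-limit correction b*ln(S/mean BVS), and
    all parameters are refit jointly with assignments fixed; assignment
    and refit iterate to a fixed point (hard EM, capped).
    """
    config = config or FitConfig()
    base_params = single_fit.params
    if bond_type not in base_params:
        raise ConfigError(f"{bond_type.label()} not present in the single fit")
    relevant: List[BindingSite] = []
    others: List[BindingSite] = []
    for site in sites:
        keys = site.resolved_keys(base_params)
        (relevant if bond_type in keys else others).append(site)
    if not relevant:
        raise ConfigError(f"no site contains bond type {bond_type.label()}")

    values = np.array([bvs(site, base_params) for site in relevant])
    histogram = np.histogram(values, bins=min(60, max(10, len(values) // 10)))
    s_expected = bond_type.oxidation_state

    if config.split_method == "valley":
        threshold = _valley_threshold(values)
        hi = values > threshold
        mu = np.array(
            [
                values[~hi].mean() if (~hi).any() else values.mean(),
                values[hi].mean() if hi.any() else values.mean(),
            ]
        )
        sigma = float(values.std())
        weights = np.array([(~hi).mean(), hi.mean()])
        in_high = hi
    else:
        mu, sigma, weights, resp = _em_two_gaussians(values)
        in_high = resp[int(np.argmax(mu))] > 0.5

    separation_vu = float(abs(mu[1] - mu[0]))
    if separation_vu < config.min_separation_vu or in_high.all() or not in_high.any():
        return SpinSplitResult(
            split=False,
            assignments={site.key: "HS" for site in relevant},
            params=base_params,
            separation=0.0,
            mixture_means=(float(mu[0]), float(mu[1])),
            mixture_sigma=sigma,
            mixture_weights=(float(weights[0]), float(weights[1])),
            bvs_values={s.key: float(v) for s, v in zip(relevant, values)},
            histogram=histogram,
            fit=single_fit,
        )

    # Higher-BVS component = LS (shorter bonds -> inflated sums).
    assignments = {
        site.key: ("LS" if high else "HS") for site, high in zip(relevant, in_high)
    }

    b = base_params.b
    r0_single = base_params.entries[bond_type].r0
    ls_key = bond_type.with_spin("LS")
    hs_key = bond_type.with_spin("HS")

    def _build_initial() -> ParameterSet:
        params = base_params.copy()
        entry = params.entries.pop(bond_type)
        mu_ls = float(values[in_high].mean())
        mu_hs = float(values[~in_high].mean())
        params.entries[ls_key] = replace(
            entry, r0=r0_single + b * math.log(s_expected / mu_ls)
        )
        params.entries[hs_key] = replace(
            entry, r0=r0_single + b * math.log(s_expected / mu_hs)
        )
        return params

    initial = _build_initial()
    fit = None
    rounds = 0
    for rounds in range(1, config.max_split_rounds + 1):
        labeled = [site.with_spin(assignments[site.key]) for site in relevant]
        fit = fit_r0(labeled + others, initial, config, filter_config)
        initial = fit.params.copy()
        # reassign: the spin class whose parameterization explains the site best
        new_assignments = {}
        for site in relevant:
            errors = {}
            for spin in ("LS", "HS"):
                candidate = site.with_spin(spin)
                errors[spin] = abs(
                    bvs(candidate, fit.params) - site.require_oxidation()
                )
            new_assignments[site.key] = min(errors, key=errors.get)
        if new_assignments == assignments:
            assignments = new_assignments
            break
        assignments = new_assignments

    assert fit is not None
    separation = abs(fit.params.entries[hs_key].r0 - fit.params.entries[ls_key].r0)
    return SpinSplitResult(
        split=True,
        assignments=assignments,
        params=fit.params,
        separation=separation,
        mixture_means=(float(mu[0]), float(mu[1])),
        mixture_sigma=sigma,
        mixture_weights=(float(weights[0]), float(weights[1])),
        bvs_values={s.key: float(v) for s, v in zip(relevant, values)},
        histogram=histogram,
        fit=fit,
        rounds=rounds,
    )
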