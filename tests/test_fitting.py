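import math

import numpy as np
import pytest

from bvfit.core import BindingSite, BondTypeKey, ParameterSet, bvs, homoleptic_r0
from bvfit.errors import ConfigError, MissingParameterError
from bvfit.fitting import (
    fit_r0,
    gradient,
    homoleptic_summary,
    objective,
    split_bimodal,
    uncertainty,
)
from bvfit.synthetic import SyntheticConfig, generate_population, generate_spin_mixture

from .conftest import make_site

B = 0.37

FE2_N = BondTypeKey("Fe", 2, "N")
FE2_O = BondTypeKey("Fe", 2, "O")


def two_type_params(r0_n=1.76, r0_o=1.70):
    params = ParameterSet()
    params.set(FE2_N, r0_n)
    params.set(FE2_O, r0_o)
    return params


def assigned(sites, state=2):
    out = []
    for site in sites:
        site = BindingSite(**{**vars(site), "oxidation_state": state,
                              "contacts": list(site.contacts)})
        out.append(site)
    return out


def population(n=200, seed=1, noise=0.0, het=0.5, jitter=8.0, **kwargs):
    config = SyntheticConfig(
        true_params=two_type_params(),
        n_sites=n,
        oxidation_state=2,
        heteroleptic_fraction=het,
        ligand_pool={"N": 0.6, "O": 0.4},
        distance_noise_sd=noise,
        partition_jitter=jitter,
        seed=seed,
        **kwargs,
    )
    sites, truth = generate_population(config)
    return assigned(sites), truth


class TestObjective:
    def test_zero_for_exact_population(self):
        sites, _ = population(n=50)
        assert objective(two_type_params(), sites) == pytest.approx(0.0, abs=1e-20)

    def test_unit_residual(self):
        # homoleptic site tuned so V = S + 1
        site = make_site([2.0] * 6, oxidation_state=2)
        r0 = 2.0 + B * math.log(3 / 6.0)  # V = 3 = S + 1
        params = ParameterSet()
        params.set(FE2_N, r0)
        assert objective(params, [site]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_site_resummation(self):
        sites = [
            make_site([2.0, 2.1], oxidation_state=2),
            make_site([1.9, 2.0, 2.2], ["N", "O", "N"], oxidation_state=2),
            make_site([2.05] * 4, ["O"] * 4, oxidation_state=3),
        ]
        params = two_type_params()
        params.set(BondTypeKey("Fe", 3, "O"), 1.76)
        expected = sum((bvs(s, params) - s.oxidation_state) ** 2 for s in sites)
        assert objective(params, sites) == pytest.approx(expected, abs=1e-14)

    def test_missing_key(self):
        site = make_site([2.0, 2.0], ["N", "S"], oxidation_state=2)
        with pytest.raises(MissingParameterError):
            objective(two_type_params(), [site])


class TestGradient:
    def test_zero_at_ground_truth(self):
        sites, _ = population(n=50)
        grad = gradient(two_type_params(), sites)
        assert all(abs(g) < 1e-10 for g in grad.values())

    def test_finite_difference_oracle(self):
        sites, _ = population(n=60, seed=5, noise=0.03)
        params = two_type_params(1.80, 1.65)
        grad = gradient(params, sites)
        step = 1e-6
        for key in (FE2_N, FE2_O):
            up = params.copy()
            up.set(key, params.entries[key].r0 + step)
            down = params.copy()
            down.set(key, params.entries[key].r0 - step)
            fd = (objective(up, sites) - objective(down, sites)) / (2 * step)
            assert grad[key] == pytest.approx(fd, rel=1e-5)

    def test_unused_type_zero_component(self):
        sites = [make_site([2.0, 2.1], oxidation_state=2)]  # N only
        grad = gradient(two_type_params(), sites)
        assert grad[FE2_O] == 0.0
        assert grad[FE2_N] != 0.0


class TestFitR0:
    def test_noise_free_homoleptic_recovery(self):
        config = SyntheticConfig(
            true_params=two_type_params(), n_sites=200, oxidation_state=2,
            ligand_pool={"N": 1.0}, partition_jitter=6.0, seed=2,
        )
        sites = assigned(generate_population(config)[0])
        initial = two_type_params(1.86, 1.734)
        fit = fit_r0(sites, initial)
        assert fit.params.entries[FE2_N].r0 == pytest.approx(1.76, abs=1e-6)
        # closed-form cross-check on each homoleptic site
        for site in sites[:20]:
            assert homoleptic_r0(site, B) == pytest.approx(1.76, abs=1e-9)

    def test_noise_free_heteroleptic_recovery(self):
        sites, _ = population(n=200, seed=3, het=1.0)
        fit = fit_r0(sites, two_type_params(1.86, 1.734))
        assert fit.params.entries[FE2_N].r0 == pytest.approx(1.76, abs=1e-6)
        assert fit.params.entries[FE2_O].r0 == pytest.approx(1.70, abs=1e-6)

    def test_noise_free_mixed_recovery(self):
        sites, _ = population(n=200, seed=4, het=0.5)
        fit = fit_r0(sites, two_type_params(1.86, 1.734))
        assert fit.params.entries[FE2_N].r0 == pytest.approx(1.76, abs=1e-6)
        assert fit.params.entries[FE2_O].r0 == pytest.approx(1.70, abs=1e-6)

    def test_trace_monotone_nonincreasing(self):
        sites, _ = population(n=150, seed=6, noise=0.02)
        fit = fit_r0(sites, two_type_params(1.86, 1.734))
        trace = fit.objective_trace
        assert all(b <= a + 1e-10 for a, b in zip(trace, trace[1:]))

    def test_poisoned_site_pruned_without_shifting_fit(self):
        sites, _ = population(n=200, seed=8)
        clean_fit = fit_r0(sites, two_type_params(1.86, 1.734))
        # plant a site with V > 2S under the true parameters
        poison = make_site([1.5] * 6, oxidation_state=2, entry_id="POISON")
        assert bvs(poison, two_type_params()) > 4
        fit = fit_r0(sites + [poison], two_type_params(1.86, 1.734))
        pruned_ids = {r.entry_id for r in fit.pruned_sites.records}
        assert "POISON" in pruned_ids
        for key in (FE2_N, FE2_O):
            assert fit.params.entries[key].r0 == pytest.approx(
                clean_fit.params.entries[key].r0, abs=1e-6
            )

    def test_pruning_stable_on_kept_set(self):
        sites, _ = population(n=100, seed=9, noise=0.05)
        fit1 = fit_r0(sites, two_type_params(1.86, 1.734))
        fit2 = fit_r0(fit1.sites_used, two_type_params(1.86, 1.734))
        for key in fit1.params.keys():
            if key in (FE2_N, FE2_O):
                assert fit2.params.entries[key].r0 == pytest.approx(
                    fit1.params.entries[key].r0, abs=1e-10
                )

    def test_noisy_bias_small_and_uncertainty_bounds(self):
        sites, _ = population(n=500, seed=10, noise=0.02, het=0.3)
        fit = fit_r0(sites, two_type_params(1.86, 1.734))
        assert abs(fit.params.entries[FE2_N].r0 - 1.76) < 0.01
        assert abs(fit.params.entries[FE2_O].r0 - 1.70) < 0.01
        # reported uncertainty bounds the spread of per-site re-estimates
        homoleptic_n = [
            homoleptic_r0(s, B)
            for s in fit.sites_used
            if s.is_homoleptic() and s.contacts[0].ligand_element == "N"
        ]
        assert fit.uncertainties[FE2_N] >= np.std(homoleptic_n) - 1e-3

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            fit_r0([], two_type_params())


class TestUncertainty:
    def test_zero_residual_population(self):
        sites, _ = population(n=50, seed=11)
        result = uncertainty(sites, two_type_params())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in result.values.values())

    def test_homoleptic_closed_form(self):
        sites = [
            make_site([2.00] * 6, entry_id="A"),
            make_site([2.10] * 6, entry_id="B"),
            make_site([2.20] * 6, entry_id="C"),
        ]
        params = ParameterSet()
        params.set(FE2_N, 1.76)
        result = uncertainty(sites, params)
        expected = math.sqrt(
            np.mean(
                [
                    (B * math.log(2.0 / bvs(s, params))) ** 2
                    for s in sites
                ]
            )
        )
        assert result.values[FE2_N] == pytest.approx(expected, abs=1e-12)

    def test_never_below_homoleptic_sd(self):
        sites, _ = population(n=300, seed=12, noise=0.03, het=0.0)
        fit = fit_r0(sites, two_type_params(1.86, 1.734))
        result = uncertainty(fit.sites_used, fit.params)
        per_site = [homoleptic_r0(s, B) for s in fit.sites_used
                    if s.contacts[0].ligand_element == "N"]
        assert result.values[FE2_N] >= np.std(per_site) - 1e-6


class TestHomolepticSummary:
    def test_single_site(self):
        site = make_site([2.0, 2.1, 2.2], oxidation_state=2)
        summary = homoleptic_summary([site], B)
        assert summary[FE2_N]["mean"] == pytest.approx(homoleptic_r0(site, B))
        assert summary[FE2_N]["sd"] == 0.0
        assert summary[FE2_N]["count"] == 1

    def test_two_sites_mean_and_sd(self):
        sites = [make_site([2.0] * 6, entry_id="A"), make_site([2.1] * 6, entry_id="B")]
        summary = homoleptic_summary(sites, B)
        values = [homoleptic_r0(s, B) for s in sites]
        assert summary[FE2_N]["mean"] == pytest.approx(np.mean(values))
        assert summary[FE2_N]["sd"] == pytest.approx(np.std(values, ddof=1))

    def test_heteroleptic_excluded(self):
        sites = [make_site([2.0, 2.0], ["N", "O"])]
        assert homoleptic_summary(sites, B) == {}

    def test_recovers_generator_r0(self):
        sites, _ = population(n=200, seed=13, noise=0.02, het=0.0)
        summary = homoleptic_summary(sites, B)
        assert summary[FE2_N]["mean"] == pytest.approx(1.76, abs=0.01)


def spin_mixture(n=500, seed=21, noise=0.02, ls_fraction=0.3):
    truth = ParameterSet()
    truth.set(BondTypeKey("Fe", 2, "N", "LS"), 1.57)
    truth.set(BondTypeKey("Fe", 2, "N", "HS"), 1.76)
    config = SyntheticConfig(
        true_params=truth, n_sites=n, oxidation_state=2,
        ligand_pool={"N": 1.0}, distance_noise_sd=noise,
        spin_populations={"ls_fraction": ls_fraction}, seed=seed,
    )
    sites, truth_ledger = generate_spin_mixture(config)
    return assigned(sites), truth_ledger


class TestSplitBimodal:
    def test_recovers_both_parameters(self):
        sites, truth = spin_mixture()
        initial = ParameterSet()
        initial.set(FE2_N, 1.86)
        single = fit_r0(sites, initial)
        split = split_bimodal(sites, FE2_N, single)
        assert split.split
        ls = split.params.entries[FE2_N.with_spin("LS")].r0
        hs = split.params.entries[FE2_N.with_spin("HS")].r0
        assert ls == pytest.approx(1.57, abs=0.02)
        assert hs == pytest.approx(1.76, abs=0.02)
        assert split.separation == pytest.approx(0.19, abs=0.03)

    def test_assignment_accuracy(self):
        sites, truth = spin_mixture()
        initial = ParameterSet()
        initial.set(FE2_N, 1.86)
        single = fit_r0(sites, initial)
        split = split_bimodal(sites, FE2_N, single)
        truth_map = {
            (row["entry_id"], row["site_id"]): row["spin_class"] for row in truth
        }
        hits = [split.assignments[k] == truth_map[k] for k in split.assignments]
        assert np.mean(hits) >= 0.95

    def test_distance_ranges_map_to_spin(self):
        """Sites with all Fe-N distances in 1.9-2.1 A land in LS; 2.1-2.3 in HS."""
        sites, _ = spin_mixture()
        initial = ParameterSet()
        initial.set(FE2_N, 1.86)
        split = split_bimodal(sites, FE2_N, fit_r0(sites, initial))
        for site in sites:
            distances = [c.distance for c in site.contacts]
            if all(1.9 <= d <= 2.1 for d in distances):
                assert split.assignments[site.key] == "LS"
            elif all(2.1 <= d <= 2.3 for d in distances):
                assert split.assignments[site.key] == "HS"

    def test_unimodal_population_declines(self):
        sites, _ = spin_mixture(ls_fraction=0.0, seed=22)
        initial = ParameterSet()
        initial.set(FE2_N, 1.86)
        single = fit_r0(sites, initial)
        split = split_bimodal(sites, FE2_N, single)
        assert not split.split
        assert split.params is single.params
        assert split.separation == 0.0

    def test_every_relevant_site_assigned(self):
        sites, _ = spin_mixture(n=200, seed=23)
        initial = ParameterSet()
        initial.set(FE2_N, 1.86)
        split = split_bimodal(sites, FE2_N, fit_r0(sites, initial))
        assert set(split.assignments) == {s.key for s in sites}
        assert set(split.assignments.values()) <= {"LS", "HS"}
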